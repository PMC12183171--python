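import numpy as np
import pytest

import agroplan as ap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def env_default():
    """Shipped default environment (2 fields, 12 steps, 8x8 grids)."""
    return ap.make_environment({}, seed=0)


@pytest.fixture
def env_noiseless():
    return ap.make_environment({"noise_scale": 0.0}, seed=0)


@pytest.fixture
def env_toy():
    """The shipped 1-field, short-horizon, noiseless toy environment."""
    return ap.simulator.toy_environment(seed=0)
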