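"""Train the constrained allocation policy on the toy environment.

A shared Gaussian policy proposes per-step doses; emitted actions are
clipped to the agronomic box and capped by the remaining budget, so every
executed season is feasible by construction.  Training uses the clipped
surrogate with generalized advantage estimation.
"""

import numpy as np

from agroplan import simulator as sim
from agroplan.allocator import TrainPolicyConfig, eval_policy, train_policy

env = sim.toy_environment(seed=0)
cfg = TrainPolicyConfig(iterations=25, episodes_per_iter=8)

state, history = train_policy(env, seed=0, train_config=cfg)
initial, _ = train_policy(env, seed=0,
                          train_config=TrainPolicyConfig(iterations=0))

r_trained, doses = eval_policy(env, state, n_episodes=50, seed=123)
r_initial, _ = eval_policy(env, initial, n_episodes=50, seed=123)

print(f"mean return during training: {history[0]['mean_return']:.0f} -> "
      f"{history[-1]['mean_return']:.0f}")
print(f"evaluation return: initial policy {r_initial:.0f}, "
      f"trained policy {r_trained:.0f} "
      f"(+{100 * (r_trained - r_initial) / abs(r_initial):.1f}%)")
print(f"mean dose: water {doses[:, 0].mean():.0f} L/ha/step, "
      f"fert {doses[:, 1].mean():.1f} kg/ha/step "
      f"(saturation at {env.saturation_dose})")
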