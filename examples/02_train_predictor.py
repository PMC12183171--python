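"""Train the spatiotemporal predictor on simulated observation sequences.

Each training pair is one field-season of multi-modal observations (gridded
channels, point sensors, weather forecasts) and its season-total outcome
triple (yield, cost, environmental impact).  Noiseless dynamics make the
mapping learnable to high accuracy at desk scale.
"""

import numpy as np

import agroplan as ap
from agroplan.predictor import TrainConfig, build_dataset, train_predictor

env = ap.make_environment({"n_fields": 1, "horizon": 6, "noise_scale": 0.0},
                          seed=0)
data = build_dataset(env, n_sequences=120, seed=0)
print(f"dataset: {len(data['targets'])} seasons, grids {data['grids'].shape[1:]}")

result = train_predictor(data, train_config=TrainConfig(epochs=80, lr=2e-2),
                         seed=0)
print(f"loss: {result.loss_history[0]:.3f} (pre-training) -> "
      f"{result.loss_history[-1]:.4f} "
      f"({100 * result.loss_history[-1] / result.loss_history[0]:.1f}%)")

pred = result.predict_outcomes(data["grids"][:3], data["sensors"][:3],
                               data["weather"][:3])
for p, t in zip(pred, data["targets"][:3]):
    print(f"predicted (Y, C, E) = ({p[0]:7.1f}, {p[1]:5.1f}, {p[2]:5.3f})   "
          f"true = ({t[0]:7.1f}, {t[1]:5.1f}, {t[2]:5.3f})")
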