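"""Prediction-driven warm start of the control plan.

Given outcome predictions, find a feasible dose plan whose noiseless
simulated outcomes track them: projected gradient descent on the tracking
objective, with every iterate projected onto the budget + dose-bound set.
"""

import numpy as np

import agroplan as ap
from agroplan.allocator import (InitConfig, initialize_controls,
                                simulated_outcomes)

env = ap.make_environment({"n_fields": 1, "horizon": 4, "noise_scale": 0.0},
                          seed=0)

# pretend the predictor forecast the outcomes of this (unknown) target plan
target_plan = np.tile([220.0, 9.0], (1, env.horizon, 1))
predictions = simulated_outcomes(env, target_plan)

plan, objective, trace = initialize_controls(
    predictions, env, InitConfig(max_iters=80, step_size=50.0, tol=1e-12))

print(f"tracking objective: {trace[0]:.1f} (start) -> {objective:.4g} "
      f"in {len(trace) - 1} accepted steps (monotone non-increasing)")
print("recovered doses per step (water L/ha, fert kg/ha):")
for t in range(env.horizon):
    w, f = plan.actions[0, t]
    print(f"  t={t}: ({w:6.1f}, {f:5.2f})   target (220.0,  9.00)")
print(f"feasible: {ap.check_constraints(plan).feasible}")
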