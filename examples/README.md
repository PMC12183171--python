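# Examples

One short script per capability; each builds a small input, runs the method
and prints what the numbers mean.  All run in seconds to ~1 minute on one
CPU.

| script | capability |
| --- | --- |
| `01_simulate_season.py` | roll out a season, audit budget/dose/impact constraints, compute the objective |
| `02_train_predictor.py` | train the conv + attention + GRU + fusion predictor on simulated seasons |
| `03_warm_start_allocation.py` | recover a feasible dose plan whose simulated outcomes track given predictions |
| `04_train_policy.py` | train the constrained Gaussian policy with the clipped surrogate and GAE |
| `05_compare_strategies.py` | compare rule-based / greedy / wasteful strategies under common random numbers |
| `06_attribution_and_economics.py` | Shapley feature attribution and adoption cost-benefit arithmetic |
| `07_weight_sweep.py` | sensitivity of the learned policy to the (yield, cost, impact) weights |

Run any of them from the repository root, e.g.
`python examples/04_train_policy.py`.
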