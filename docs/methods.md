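# Methods

`agroplan` studies a two-stage decision pipeline for precision agriculture —
predict field outcomes from multi-modal observations, then allocate water and
fertilizer under budget, agronomic and environmental constraints — inside a
fully synthetic farm environment whose ground truth is known in closed form.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic setting can and cannot show.

## The farm environment

**State.** Each of `m` fields carries, per step `t` of a `T`-step season, a
state `S = {d, e, r, h}` plus a latent soil-moisture fraction:

* `d` — crop vector: growth stage, health, phenotype score, each in [0, 1];
* `e` — environment: temperature (degC), humidity (fraction), precipitation
  (mm/step);
* `r` — cumulative resource use: water (L/ha), fertilizer (kg/ha), pesticide
  (unused by the default action space);
* `h` — history lags: last-step yield accrual, water dose, fertilizer dose.

Internally time is 0-based over `{0..T-1}`; grids are row-major,
channel-last `(H, W, C)`.

**Transition** `S' = Phi(S, u) + eps`, with `u = (water, fert)` doses per
hectare per step:

* moisture' = `(1 - delta) * moisture + kappa_irr * u_water + kappa_rain *
  precip`, clipped to [0, 1].  Defaults: decay `delta = 0.3`, irrigation
  efficiency `kappa_irr = 5e-4` per L/ha (a 400 L/ha application raises
  moisture by 0.2), rain efficiency `0.01` per mm;
* health relaxes at rate 0.5 toward a moisture-optimum target
  `exp(-((moisture - 0.55) / 0.30)^2)` — both drought and water-logging
  depress the crop;
* growth advances logistically, `growth' = growth + 0.15 * health *
  (1 - growth)`; the phenotype score is a slow moving average of health;
* weather is AR(1) around its means (temperature 22 degC, autocorrelation
  0.7; humidity 0.6; precipitation follows a seasonal sinusoid around
  8 mm/step);
* `eps` is zero-mean Gaussian with per-component scales, all multiplied by a
  global `noise_scale`; bounded components are **clipped after** the noise,
  so the noise is exactly zero-mean only on interior states (the Monte-Carlo
  test uses interior states for this reason).  `noise_scale = 0` makes every
  map deterministic.

**Outcomes.** Per (field, step), for dose `u`:

* yield accrual `Y = Y0 * health * (1 + sum_k beta_k * g_k(u_k))` with
  baseline `Y0 = 330` kg/ha/step, gains `beta = (0.40, 0.25)` and the
  saturating response `g_k(u) = 1 - (1 - min(u, u_sat,k)/u_sat,k)^q`,
  `q = 2`.  The response is concave, non-decreasing, and exactly flat at and
  above the saturation doses `u_sat = (400 L/ha, 15 kg/ha)` — extra input
  buys nothing;
* cost `C = u . p` with prices `p = (0.02 $/L, 0.5 $/kg)`;
* environmental impact `E = sum_k c_k * max(0, u_k - u_sat,k)^2`, a convex
  penalty on over-application (`c = (1e-5, 5e-3)`).

Defaults put a season at roughly 2,500–4,000 kg/ha of yield accrual and tens
of dollars of per-hectare input cost, the scale of a broad-acre crop.  The
season objective is `J = sum_i sum_t [a1*Y - a2*C - a3*E]`, identical to the
sum of per-step rewards; constraints are a season-wide budget
`sum u <= B` (default 7,000, summed across fields, steps and resource
kinds), per-kind dose bounds (water in [0, 600] L/ha, fertilizer in
[0, 25] kg/ha per step) and a per-step cap `E <= E_max = 5`.

An important emergent property: because over-irrigation pushes moisture past
the optimum and depresses health, the *yield-maximizing* water dose sits
well below saturation (about 190 L/ha/step in the toy environment).  Tests
that check the policy recovers "the simulator's known optimum" compute that
optimum by grid search rather than assuming it equals the saturation dose.

**Observations.** Each (field, step) yields a multi-modal bundle: an
`H x W x C` grid (vegetation index, soil moisture, precipitation,
temperature, past water use), a point-sensor vector (two channels at three
fixed positions plus cumulative water/fertilizer application readings), and
a weather forecast (`e` plus forecast error).  Grid channels are the latent
scalar driver modulated by a smooth low-frequency random field whose
amplitude scales with `noise_scale`, plus per-cell noise; at zero noise each
channel is exactly constant at its driver value, which is what the
degenerate-field tests assert.

## The predictor

Per step: same-padded stride-1 convolutions (default one layer of 4–6
channels, LeakyReLU slope 0.01), 2x2 non-overlapping max pooling, then
spatial self-attention over the pooled positions
(`softmax(Q K^T / sqrt(d)) V`, default `d = 8`).  The flattened attended
features drive a GRU (default hidden 16–24) across the season.  A config
switch `gru_input` lets the recurrence read either the attended pooled
features (`"p_att"`, default, so pooling/attention sit on the data path) or
the flattened first convolution output (`"z1"`).

The final hidden state, last-step sensor vector and last-step forecast are
each encoded by a one-layer tanh map to a shared embedding length, fused by
modality attention (`alpha_k = softmax_k(q^T W_k M_k)`, `f = sum alpha_k
M_k`; the bilinear score requires vector modalities and the sum requires a
shared length, hence the encoders), and a small fully connected head emits
`(Yhat, Chat, Ehat)`.  A softmax classifier head over the fused embedding is
provided for categorical targets.

**Loss and optimization.** The multi-task loss sums per-task squared errors
with weights `lambda_k`; the dynamic scheme sets `lambda_k = 1/sigma_k^2`,
where `sigma_k` is the trailing-window (default 10 batches) standard
deviation of each task's per-batch loss, normalized to mean 1 so it
rebalances without changing the loss scale — the estimator for `sigma_k` is
a design choice of this package.  Training uses global-norm gradient
clipping and AdamW (decoupled weight decay); bias correction is applied by
default, with `bias_correction=False` available for the raw moment-ratio
update.  Targets are standardized inside the trainer (scaler returned with
the fit).  Desk-scale defaults: learning rate 1e-2 with cosine annealing to
1/100th, batch 64; the production-scale starting point would be 1e-4 with
weight decay 1e-2.  All neural components run on the package's own
reverse-mode autodiff over float64 numpy, which keeps oracle comparisons
meaningful at 1e-10 and finite-difference checks at 1e-4.

**Training data.** `build_dataset` simulates single-field seasons under a
management regime per sequence: the default "constant" policy draws one dose
pair uniform in [0, 1.25 x saturation] and applies it all season (the
over-saturation range keeps the environmental-impact task non-degenerate).
Targets are season totals of (Y, C, E).  With per-step i.i.d. doses the
final step's dose is unobservable from pre-decision observations and the
regression has irreducible error; the constant regime removes it, which is
what makes the "loss falls below 1% of initial" convergence check a test of
the model rather than of the noise floor.

## The allocator

**Warm start.** Given outcome predictions, initialization solves
`min_u sum lambda_k ||O_k(u) - Ohat_k||^2 + rho * sum_t ||u_t - u_{t-1}||^2`
over the feasible set, where `O(u)` are the *noiseless simulated* outcome
maps — the interpretation that makes the tracking problem a well-posed
function of `u`.  The solver is projected gradient descent with
central-difference gradients (one-sided at the non-negativity boundary) and
backtracking halving of the step, so the accepted-objective trace is
monotone non-increasing.  Projection onto {box} ∩ {sum u <= B} uses the
exact KKT form `clip(u - tau, lo, hi)` with `tau` found by bisection: it is
the true Euclidean projection, idempotent, and lands on the budget face to
1e-9 when the budget binds.

**Policy.** A diagonal Gaussian over the normalized action box: a two-layer
tanh network maps ~15 state features (crop, weather, normalized cumulative
resources, history, moisture, time, previous action) to a sigmoid-squashed
mean; a global learned log-std (init -1) sets exploration.  Sampled actions
are clipped to the box, scaled to physical doses and capped by the remaining
per-field season budget, so every executed plan passes the constraint
checker by construction.  Log-probabilities are recorded for the raw
pre-clip sample, the standard practice for clipped Gaussian policies.

**Updates.** GAE advantages (backward recursion, provably equal to the
double sum) with `gamma = 0.99`, `lambda = 0.95`; clipped surrogate with
`eps = 0.2`; value loss weight `c1 = 0.5`; entropy bonus `c2 = 0.01` using
the closed-form Gaussian entropy; 4 surrogate epochs per batch — standard
values, since none are prescribed by the problem.  The total is minimized as
`-L_clip + c1*L_V - c2*H`.  Rewards are scaled by 1e-2 during collection
(advantage normalization makes this a conditioning choice only; returns are
reported in physical units).  The anchored feedback adds
`lambda_anchor * mean ||mu_theta(s) - u0(s)||^2` through the policy mean at
visited states — the differentiable route from the plan-space penalty to
policy parameters; `lambda_anchor = 0` reproduces the plain update exactly
(bit for bit, same seed).  Each field is an independent episode of a shared
policy.  The risk-aware selector `argmax_k mean(R_k) - alpha * var(R_k)`
(unbiased sample variance, ties to the lowest index) is an optional
evaluation-time overlay, not part of the training loop.

## Evaluation apparatus

* Heuristics: the threshold rule irrigates a fixed 300 L/ha when moisture
  drops below 0.45 and fertilizes 12 kg/ha while cumulative use lags a
  pro-rata 150 kg/ha seasonal schedule; the greedy strategy takes the best
  one-step noiseless reward over a candidate dose grid (ties to the smallest
  dose).  Their reported numbers are environment-specific; only qualitative
  orderings are asserted.
* Strategy comparison uses common random numbers (the same episode seeds for
  every strategy), so differences reflect policy, not draws.  The
  "adaptability" column is a proxy: the fraction of mean reward retained
  when precipitation drops to a quarter and temperature rises 4 degC,
  unannounced, at mid-season.  Decision latency is wall-clock and
  informational only — it is excluded from determinism comparisons.
* Classification metrics are the standard accuracy/recall/F1 plus AUC by the
  Mann-Whitney midrank statistic (tie-corrected), tested against exhaustive
  positive-negative pair counting.
* Shapley attribution uses permutation sampling with background
  marginalization.  Background rows are cycled (stratified) rather than
  drawn i.i.d., which removes the background-sampling variance component —
  for a linear model the estimate then converges to
  `w_j (x_j - mean b_j)` at machine precision once full cycles complete.
  The efficiency residual `|sum phi - (f(x) - mean f(bg))|` is always
  computed and reported.
* The weight sweep normalizes each `(a1, a2, a3)` row to the simplex, trains
  a short policy per cell and reports the achieved score plus raw outcome
  components.

## Numerical choices

* Everything is float64.  Softmaxes are computed via a max-shifted
  log-softmax; gate values and probabilities are asserted to sum to 1 within
  1e-12 in tests.
* Max pooling splits gradients evenly across tied maxima (keeps
  finite-difference checks symmetric); ratio clipping passes zero gradient
  outside the clip band.
* Finite-difference gradient checks use step 1e-5 with a denominator floor
  of 1e-6: central differences on an O(1) loss carry ~1e-11 cancellation
  noise, so components with gradients below ~1e-6 cannot be resolved to
  better than 1e-4 relative and would otherwise produce spurious failures
  even when the analytic gradient is exact.
* The budget-projection bisection runs to a 1e-12 relative bracket, well
  inside the 1e-9 budget-face tolerance asserted in tests.
* Degenerate inputs are errors, not silent fixes: negative doses, horizon
  overrun, ragged trajectories, non-finite gradients (the optimizer refuses
  the step), single-class AUC, sub-2-sample variance estimates.

## Problem sizes

Desk scale throughout, chosen so the full suite and the acceptance script
each run in minutes on one CPU: 8x8 grids with 5 channels, seasons of 6–12
steps, 1–2 fields, hidden sizes 16–32.  Predictor convergence runs use 500
noiseless single-field seasons of 6 steps (250 epochs); policy runs use the
shipped toy environment (1 field, 8 steps, noiseless, budget 4,000) with 25
iterations of 8 seasons, evaluated over 100 episodes.  Every component
accepts larger sizes through its config.

## What passing tests do and do not show

The generator produces smooth, low-dimensional, well-specified dynamics with
Gaussian noise and exactly known response curves.  Passing the suite shows
the equations are implemented correctly, optimization behaves as designed,
and the pipeline's pieces compose; it does not show that the predictor or
policy would perform on real fields, where dynamics are non-stationary,
observations are missing or biased, response curves vary by soil and
cultivar, and the action space is richer.  Real remote-sensing ingestion,
GIS integration and multi-farm deployment are out of scope by design.

## Known limitations

* The warm-start gradient is numerical (central differences over the
  rollout), fine at desk scale but quadratic-cost in plan size; an adjoint
  pass through the simulator would be the scaling route.
* The per-field budget split during rollouts is a fixed equal share;
  cross-field reallocation is representable in `ControlPlan` but not
  exploited by the shipped policy.
* The dynamic uncertainty weighting estimates `sigma_k` from batch-loss
  dispersion, one of several defensible readings of "task uncertainty"; it
  is exposed but off by default.
* `eps` enters additively on bounded state components and is clipped;
  near the bounds the effective noise is therefore truncated rather than
  exactly Gaussian.
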