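"""Evaluation apparatus: heuristic baselines, metrics, attribution, economics.

Covers the comparison protocol between the learned allocator and simple
heuristics (threshold rules and one-step greedy lookahead), standard binary
classification metrics with a rank-statistic AUC, permutation-sampling
Shapley feature attribution with an efficiency-residual diagnostic, the
plain cost-benefit arithmetic of adoption, and a sensitivity sweep over the
objective weights on the simplex.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import simulator as sim

__all__ = [
    "RuleThresholds", "rule_based_policy", "greedy_policy",
    "compare_strategies", "classification_metrics", "AttributionResult",
    "shapley_attribution", "cost_benefit", "sensitivity_sweep",
]


# ---------------------------------------------------------------------------
# heuristic baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleThresholds:
    """Trigger levels and fixed doses for the threshold heuristic."""

    moisture_threshold: float = 0.45
    irrigation_dose: float = 300.0     # L/ha applied when soil is dry
    fert_season_target: float = 150.0  # kg/ha spread evenly over the season
    fert_dose: float = 12.0            # kg/ha applied while behind schedule


def rule_based_policy(state: sim.FieldState, env: sim.EnvironmentParams,
                      thresholds: RuleThresholds | None = None) -> np.ndarray:
    """Deterministic threshold rule: irrigate when dry, fertilize on schedule.

    Water: fixed dose when latent soil moisture is below the trigger, else 0.
    Fertilizer: fixed dose while cumulative use lags the pro-rata seasonal
    target, else 0.
    """
    th = thresholds or RuleThresholds()
    water = th.irrigation_dose if state.soil_moisture < th.moisture_threshold else 0.0
    schedule = th.fert_season_target * (state.time + 1) / env.horizon
    fert = th.fert_dose if state.resources[sim.FERT] < schedule else 0.0
    return np.array([water, fert])


def greedy_policy(state: sim.FieldState, env: sim.EnvironmentParams,
                  candidate_grid: np.ndarray,
                  weights: sim.ObjectiveWeights | None = None) -> np.ndarray:
    """One-step lookahead: the candidate dose with the best noiseless reward.

    Ties resolve to the earliest (smallest) candidate, since the scan keeps
    the first strict maximum.
    """
    candidates = np.atleast_2d(np.asarray(candidate_grid, dtype=float))
    if len(candidates) == 0:
        raise ValueError("candidate grid must be non-empty")
    weights = weights or sim.ObjectiveWeights()
    best, best_r = 0, -np.inf
    for k, a in enumerate(candidates):
        r = sim.reward(sim.outcome(env, state, a), weights)
        if r > best_r:
            best, best_r = k, r
    return candidates[best]


def default_candidate_grid(env: sim.EnvironmentParams, n: int = 5) -> np.ndarray:
    """Cartesian dose grid from zero to saturation for each resource kind."""
    axes = [np.linspace(0, s, n) for s in env.saturation_dose]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def _shifted_env(env: sim.EnvironmentParams) -> sim.EnvironmentParams:
    """Unannounced mid-season weather shift used by the adaptability proxy."""
    return replace(env, precip_mean=env.precip_mean * 0.25,
                   temp_mean=env.temp_mean + 4.0)


def _run_episode(env: sim.EnvironmentParams, strategy, seed: int,
                 weights: sim.ObjectiveWeights,
                 shift_at: int | None = None) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    states = sim.initial_states(env, rng)
    total = {"yield": 0.0, "water": 0.0, "fert": 0.0, "env": 0.0,
             "reward": 0.0, "latency": 0.0}
    n_dec = 0
    cur_env = env
    for t in range(env.horizon):
        if shift_at is not None and t == shift_at:
            cur_env = _shifted_env(env)
        nxt = []
        for s in states:
            t0 = time.perf_counter()
            a = np.asarray(strategy(s, cur_env), dtype=float)
            total["latency"] += time.perf_counter() - t0
            n_dec += 1
            out = sim.outcome(cur_env, s, a)
            total["yield"] += out.yield_
            total["water"] += a[sim.WATER]
            total["fert"] += a[sim.FERT]
            total["env"] += out.env_impact
            total["reward"] += sim.reward(out, weights)
            nxt.append(sim.step(cur_env, s, a, rng))
        states = nxt
    total["latency"] = total["latency"] / max(n_dec, 1)
    # per-field seasonal averages
    for k in ("yield", "water", "fert", "env", "reward"):
        total[k] /= env.n_fields
    return total


def compare_strategies(env: sim.EnvironmentParams,
                       strategies: Mapping[str, Callable],
                       episodes: int = 20, seed: int = 0,
                       weights: sim.ObjectiveWeights | None = None,
                       adaptability: bool = True) -> pd.DataFrame:
    """Seed-matched episode batches per strategy (common random numbers).

    Each strategy is a callable ``(state, env) -> action``.  The report has
    one row per strategy with mean/sd seasonal yield (kg/ha), water (L/ha),
    fertilizer (kg/ha), environmental impact, reward, mean decision latency
    (informational only), and an adaptability proxy: the fraction of mean
    reward retained under an unannounced mid-season weather shift.
    """
    if not strategies:
        raise ValueError("need at least one strategy")
    weights = weights or sim.ObjectiveWeights()
    rows = []
    for name, strat in strategies.items():
        runs = [_run_episode(env, strat, seed + e, weights)
                for e in range(episodes)]
        df = pd.DataFrame(runs)
        row = {"strategy": name, "episodes": episodes, "seed": seed}
        for k in ("yield", "water", "fert", "env", "reward"):
            row[f"{k}_mean"] = df[k].mean()
            row[f"{k}_sd"] = df[k].std(ddof=1) if episodes > 1 else 0.0
        row["latency_mean_s"] = df["latency"].mean()
        if adaptability:
            shifted = [_run_episode(env, strat, seed + e, weights,
                                    shift_at=env.horizon // 2)
                       for e in range(episodes)]
            base = df["reward"].mean()
            shift = float(np.mean([r["reward"] for r in shifted]))
            row["adaptability"] = shift / base if abs(base) > 1e-12 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def classification_metrics(labels: np.ndarray, scores: np.ndarray,
                           threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, recall, F1 and AUC for binary labels and continuous scores.

    AUC uses the Mann-Whitney rank statistic with midranks, which handles
    tied scores; it requires at least one positive and one negative label.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")

    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = float(np.mean(pred == y))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    ranks = rankdata(s)   # midranks correct for ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"accuracy": accuracy, "recall": float(recall), "f1": float(f1),
            "auc": float(auc)}


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Per-feature Shapley estimates with an efficiency diagnostic."""

    values: np.ndarray            # phi_j per feature
    efficiency_residual: float    # |sum phi - (f(x) - mean f(background))|
    n_samples: int
    seed: int
    prediction: float
    background_mean: float


def shapley_attribution(predict_fn: Callable[[np.ndarray], np.ndarray],
                        instance: np.ndarray, background: np.ndarray,
                        n_samples: int = 2000, seed: int = 0,
                        ) -> AttributionResult:
    """Permutation-sampling Shapley values with background marginalization.

    Each sample draws a random feature ordering and a random background row;
    features are switched from background to instance values along the
    ordering, and each feature is credited with the induced change in the
    prediction.  Per permutation the credits telescope to
    f(x) - f(background row), so the averaged attributions satisfy the
    efficiency property up to Monte-Carlo error, which is reported.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be non-empty")
    x = np.asarray(instance, dtype=float).ravel()
    d = x.size
    rng = np.random.default_rng(seed)

    try:
        f_x = float(np.asarray(predict_fn(x[None, :])).ravel()[0])
        bg_preds = np.asarray(predict_fn(background)).ravel()
    except Exception as exc:  # pragma: no cover - propagated with context
        raise RuntimeError("prediction function failed during attribution") from exc
    bg_mean = float(bg_preds.mean())

    phi = np.zeros(d)
    for s in range(n_samples):
        order = rng.permutation(d)
        # cycle the background rows (stratified rather than i.i.d. draws):
        # every full pass contributes the exact background mean, which
        # removes the background-sampling variance component
        b = background[s % len(background)]
        z = b.copy()
        prev = float(np.asarray(predict_fn(z[None, :])).ravel()[0])
        for j in order:
            z[j] = x[j]
            cur = float(np.asarray(predict_fn(z[None, :])).ravel()[0])
            phi[j] += cur - prev
            prev = cur
    phi /= n_samples

    residual = abs(phi.sum() - (f_x - bg_mean))
    return AttributionResult(values=phi, efficiency_residual=float(residual),
                             n_samples=n_samples, seed=seed, prediction=f_x,
                             background_mean=bg_mean)


# ---------------------------------------------------------------------------
# cost-benefit arithmetic
# ---------------------------------------------------------------------------

def cost_benefit(baseline_cost_per_ha: float, reduction_fraction: float,
                 area_ha: float, yield_gain_fraction: float = 0.0,
                 ) -> dict[str, float]:
    """Adoption economics: per-hectare and total seasonal savings.

    ``per_ha_saving = baseline * reduction``; ``total_saving = per_ha * area``;
    the yield-gain fraction is carried through for reporting.  Exact
    arithmetic, no modelling.
    """
    if not 0.0 <= reduction_fraction <= 1.0:
        raise ValueError(f"reduction fraction must lie in [0, 1], got {reduction_fraction}")
    if not 0.0 <= yield_gain_fraction <= 1.0:
        raise ValueError(f"yield gain fraction must lie in [0, 1], got {yield_gain_fraction}")
    if area_ha <= 0:
        raise ValueError(f"area must be > 0, got {area_ha}")
    per_ha = baseline_cost_per_ha * reduction_fraction
    return {
        "baseline_cost_per_ha": float(baseline_cost_per_ha),
        "reduction_fraction": float(reduction_fraction),
        "per_ha_saving": float(per_ha),
        "total_saving": float(per_ha * area_ha),
        "area_ha": float(area_ha),
        "yield_gain_fraction": float(yield_gain_fraction),
    }


# ---------------------------------------------------------------------------
# objective-weight sensitivity sweep
# ---------------------------------------------------------------------------

def sensitivity_sweep(env: sim.EnvironmentParams, weight_grid: np.ndarray,
                      episodes_per_cell: int = 10, seed: int = 0,
                      train_iterations: int = 8,
                      episodes_per_iter: int = 4) -> pd.DataFrame:
    """Short policy run + evaluation per (a1, a2, a3) cell on the simplex.

    Grid weights must be non-negative; each row is normalized to sum to 1.
    Returns a table with one row per cell: the composite score (mean episode
    return under that cell's weights) and the raw mean yield, cost and
    environmental impact.  Fully seeded.
    """
    from .allocator.training import TrainPolicyConfig, eval_policy, train_policy

    grid = np.atleast_2d(np.asarray(weight_grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("weights must be non-negative")
    sums = grid.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("each weight row must have a positive sum")
    grid = grid / sums

    rows = []
    for cell, (a1, a2, a3) in enumerate(grid):
        w = sim.ObjectiveWeights(a1, a2, a3)
        tc = TrainPolicyConfig(iterations=train_iterations,
                               episodes_per_iter=episodes_per_iter, weights=w)
        state, _ = train_policy(env, seed=seed, train_config=tc)
        score, _doses = eval_policy(env, state, episodes_per_cell,
                                    seed=seed + 10_000, weights=w)
        # raw outcome components under the trained policy
        raw = _raw_outcome_means(env, state, episodes_per_cell, seed + 20_000)
        rows.append({"alpha1": a1, "alpha2": a2, "alpha3": a3,
                     "score": score, **raw, "seed": seed})
    return pd.DataFrame(rows)


def _raw_outcome_means(env, state, episodes, seed) -> dict[str, float]:
    from .allocator.training import eval_policy

    totals = {"yield_mean": 0.0, "cost_mean": 0.0, "env_mean": 0.0}
    rng = np.random.default_rng(seed)
    for _ep in range(episodes):
        inits = sim.initial_states(env, rng)
        for s0 in inits:
            s = s0.copy()
            prev = np.zeros(env.n_actions)
            remaining = env.budget / env.n_fields
            for t in range(env.horizon):
                f = sim.state_features(s, env, prev)
                raw, _ = state.policy.sample(f[None, :], rng, deterministic=True)
                from .allocator.training import _emit_dose
                dose = _emit_dose(env, raw[0], remaining)
                remaining -= dose.sum()
                out = sim.outcome(env, s, dose)
                totals["yield_mean"] += out.yield_
                totals["cost_mean"] += out.cost
                totals["env_mean"] += out.env_impact
                s = sim.step(env, s, dose, rng)
                prev = dose
    n = episodes * env.n_fields
    return {k: v / n for k, v in totals.items()}
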