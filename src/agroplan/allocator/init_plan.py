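"""Prediction-driven initialization of the control plan.

The warm start solves a relaxed tracking problem: find a feasible plan whose
*noiseless simulated* outcomes match the predictor's estimates,

    min_u  l1 ||Y(u) - Yhat||^2 + l2 ||C(u) - Chat||^2 + l3 ||E(u) - Ehat||^2
           + rho * sum_t ||u_t - u_{t-1}||^2,

where Y(u), C(u), E(u) are the simulator's outcome maps evaluated along the
deterministic rollout (this is what makes the tracking objective a
well-posed function of u).  The solver is projected gradient descent with
central-difference gradients and backtracking line search, so the objective
is non-increasing across accepted iterations and every iterate is feasible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .. import simulator as sim
from .projection import project_box_budget

__all__ = ["InitConfig", "plan_tracking_objective", "refine_controls",
           "initialize_controls"]


@dataclass(frozen=True)
class InitConfig:
    """Weights and solver knobs for the warm-start tracking problem."""

    lambdas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rho: float = 0.0                # smoothness weight on ||u_t - u_{t-1}||^2
    step_size: float = 1.0
    max_iters: int = 60
    tol: float = 1e-8
    fd_step: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.lambdas) < 0 or self.rho < 0 or self.step_size < 0:
            raise ValueError("init weights and step size must be non-negative")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


def _noiseless(env: sim.EnvironmentParams) -> sim.EnvironmentParams:
    return dataclasses.replace(env, noise_scale=0.0)


def simulated_outcomes(env: sim.EnvironmentParams, actions: np.ndarray,
                       init: list[sim.FieldState] | None = None) -> np.ndarray:
    """Noiseless (m, T, 3) outcome array for a fixed action plan."""
    env0 = _noiseless(env)
    plan = sim.ControlPlan.zeros(env0)
    plan.actions = np.asarray(actions, dtype=float)
    if init is None:
        init = [sim.baseline_state(env0, i) for i in range(env0.n_fields)]
    traj = sim.rollout(env0, plan, rng=np.random.default_rng(0), init=init)
    return traj.outcome_array()


def plan_tracking_objective(actions: np.ndarray, env: sim.EnvironmentParams,
                            predictions: np.ndarray, cfg: InitConfig,
                            prev_plan: np.ndarray | None = None,
                            init: list[sim.FieldState] | None = None) -> float:
    """The relaxed tracking objective at a given action plan.

    ``predictions`` is the predictor's (m, T, 3) triple; ``prev_plan`` gives
    u_{t-1} for t = 0 (defaults to zeros, i.e. no action before the season).
    """
    actions = np.asarray(actions, dtype=float)
    out = simulated_outcomes(env, actions, init)
    lam = np.asarray(cfg.lambdas)
    err = ((out - np.asarray(predictions)) ** 2 * lam).sum()
    if cfg.rho > 0:
        first_prev = (np.zeros_like(actions[:, 0]) if prev_plan is None
                      else np.asarray(prev_plan, dtype=float)[:, 0])
        shifted = np.concatenate([first_prev[:, None], actions[:, :-1]], axis=1)
        err += cfg.rho * ((actions - shifted) ** 2).sum()
    return float(err)


def _fd_gradient(f, u: np.ndarray, h: float,
                 lower: np.ndarray | float = 0.0) -> np.ndarray:
    """Central differences, one-sided where the probe would leave the domain."""
    g = np.zeros_like(u)
    flat = u.ravel()
    gf = g.ravel()
    lo = np.broadcast_to(np.asarray(lower, dtype=float), u.shape).ravel()
    for j in range(flat.size):
        orig = flat[j]
        xp = orig + h
        xm = max(orig - h, lo[j])
        flat[j] = xp
        fp = f(u)
        flat[j] = xm
        fm = f(u)
        flat[j] = orig
        gf[j] = (fp - fm) / (xp - xm)
    return g


def refine_controls(plan: sim.ControlPlan, objective_fn, cfg: InitConfig,
                    ) -> tuple[sim.ControlPlan, list[float]]:
    """Projected gradient descent with backtracking on an arbitrary objective.

    ``objective_fn(actions) -> float`` must be defined on the feasible set.
    Returns the refined plan and the (non-increasing) accepted-objective
    trace.  Step size halves on objective increase; stops at ``cfg.tol``
    relative improvement or the iteration cap.
    """
    u = plan.actions.copy()
    lo, hi, budget = plan.dose_lower, plan.dose_upper, plan.budget
    u = project_box_budget(u, lo, hi, budget)
    obj = float(objective_fn(u))
    trace = [obj]
    eta = cfg.step_size

    for _ in range(cfg.max_iters):
        g = _fd_gradient(objective_fn, u, cfg.fd_step, lower=lo)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in plan refinement")
        gscale = max(float(np.abs(g).max()), 1e-30)
        improved = False
        trial_eta = eta
        for _bt in range(40):
            cand = project_box_budget(u - (trial_eta / gscale) * g, lo, hi, budget)
            cand_obj = float(objective_fn(cand))
            if cand_obj <= obj:
                improved = True
                break
            trial_eta *= 0.5
        if not improved:
            break
        moved = float(np.abs(cand - u).max())
        rel_gain = (obj - cand_obj) / max(abs(obj), 1e-12)
        u, obj = cand, cand_obj
        trace.append(obj)
        eta = min(trial_eta * 2.0, cfg.step_size)
        if rel_gain < cfg.tol and moved < np.sqrt(cfg.tol):
            break

    out = plan.copy()
    out.actions = u
    return out, trace


def initialize_controls(predictions: np.ndarray, env: sim.EnvironmentParams,
                        cfg: InitConfig | None = None,
                        prev_plan: np.ndarray | None = None,
                        start: sim.ControlPlan | None = None,
                        init_states: list[sim.FieldState] | None = None,
                        ) -> tuple[sim.ControlPlan, float, list[float]]:
    """Solve the warm-start tracking problem; returns (plan u0, objective, trace).

    The starting point defaults to the mid-saturation feasible plan (projected).
    """
    cfg = cfg or InitConfig()
    predictions = np.asarray(predictions, dtype=float)
    if not np.all(np.isfinite(predictions)):
        raise ValueError("predictions must be finite")
    if env.budget < 0:
        raise ValueError("infeasible constraint set: negative budget")

    if start is None:
        start = sim.ControlPlan.zeros(env)
        start.actions[:] = 0.5 * np.asarray(env.saturation_dose)

    def objective_fn(u):
        return plan_tracking_objective(u, env, predictions, cfg,
                                       prev_plan=prev_plan, init=init_states)

    plan, trace = refine_controls(start, objective_fn, cfg)
    return plan, trace[-1], trace
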