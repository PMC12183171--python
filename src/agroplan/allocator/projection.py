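"""Euclidean projection onto the feasible control set.

The feasible set is the intersection of the per-dose box [lower, upper] with
the budget half-space {sum u <= B}.  Its Euclidean projection has the closed
KKT form  x = clip(u - tau, lower, upper)  with tau = 0 when the box-clipped
point already fits the budget, and otherwise the unique tau > 0 that puts the
projection on the budget face; tau is found by bisection (the face sum is
continuous and non-increasing in tau).  The projection is idempotent and
exact on the budget face.
"""

from __future__ import annotations

import numpy as np

from ..simulator import ControlPlan

__all__ = ["project_box_budget", "project_feasible"]


def project_box_budget(u: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                       budget: float, tol: float = 1e-12) -> np.ndarray:
    """Euclidean projection of ``u`` onto {lower <= x <= upper, sum x <= budget}."""
    u = np.asarray(u, dtype=float)
    lower = np.broadcast_to(np.asarray(lower, dtype=float), u.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), u.shape)
    if np.any(lower > upper):
        raise ValueError("empty feasible set: lower bound exceeds upper bound")
    if float(lower.sum()) > budget + 1e-9:
        raise ValueError("empty feasible set: lower bounds already exceed the budget")

    x = np.clip(u, lower, upper)
    if x.sum() <= budget + tol:
        return x

    def face_sum(tau: float) -> float:
        return float(np.clip(u - tau, lower, upper).sum())

    lo, hi = 0.0, float(np.max(u - lower)) + 1.0
    while face_sum(hi) > budget:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if face_sum(mid) > budget:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return np.clip(u - hi, lower, upper)


def project_feasible(plan: ControlPlan) -> ControlPlan:
    """Project a plan's actions onto its own feasible set (budget + dose box)."""
    if not np.all(np.isfinite(plan.actions)):
        raise ValueError("plan actions must be finite")
    out = plan.copy()
    out.actions = project_box_budget(plan.actions, plan.dose_lower,
                                     plan.dose_upper, plan.budget)
    return out
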