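"""Multi-task loss and dynamic uncertainty weighting.

The predictor is trained on three tasks at once — yield, cost and
environmental impact — with squared-error terms weighted by (lambda_1,
lambda_2, lambda_3).  The dynamic weighting rule sets lambda_k = 1/sigma_k^2,
where sigma_k is an estimate of each task's uncertainty; here sigma_k is the
running standard deviation of the task's per-batch loss over a trailing
window (the estimator itself is a modelling choice, documented in the
methods note).
"""

from __future__ import annotations

from collections import deque

import numpy as np

from ..autodiff import Tensor, as_tensor

__all__ = ["multitask_loss", "uncertainty_weights", "TaskUncertaintyTracker"]


def multitask_loss(predictions: Tensor | np.ndarray, targets: np.ndarray,
                   lambdas: tuple[float, float, float] = (1.0, 1.0, 1.0),
                   ) -> Tensor:
    """L = sum_samples [l1*(Y-Yhat)^2 + l2*(C-Chat)^2 + l3*(E-Ehat)^2].

    ``predictions`` and ``targets`` are (n, 3) (any leading shape is summed
    over); the loss is >= 0 and zero iff predictions are exact.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.shape != (3,):
        raise ValueError("lambdas must be a length-3 tuple")
    if np.any(lam < 0):
        raise ValueError(f"task weights must be non-negative, got {lambdas}")
    pred = as_tensor(predictions)
    tgt = np.asarray(targets, dtype=float)
    if pred.shape != tgt.shape:
        raise ValueError(f"shape mismatch: predictions {pred.shape}, targets {tgt.shape}")
    diff = pred - tgt
    return (diff * diff * lam).sum()


def per_task_losses(predictions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Unweighted per-task summed squared errors (length 3), for tracking."""
    d = np.asarray(predictions) - np.asarray(targets)
    return (d ** 2).reshape(-1, 3).sum(axis=0)


def uncertainty_weights(sigmas) -> np.ndarray:
    """lambda_k = 1 / sigma_k^2 for each per-task uncertainty sigma_k > 0."""
    s = np.asarray(sigmas, dtype=float)
    if np.any(s <= 0):
        raise ValueError(f"task uncertainties must be > 0, got {sigmas}")
    return 1.0 / s**2


class TaskUncertaintyTracker:
    """Running per-task loss-std estimator feeding the dynamic weights.

    Keeps a trailing window of per-batch task losses; ``sigmas`` is their
    standard deviation (floored to avoid degenerate weights early on) and
    ``weights`` the resulting lambda_k, normalized to mean 1 so the dynamic
    scheme rebalances tasks without changing the overall loss scale.
    """

    def __init__(self, window: int = 10, floor: float = 1e-3):
        self.window = int(window)
        self.floor = float(floor)
        self._hist: deque[np.ndarray] = deque(maxlen=self.window)

    def update(self, task_losses: np.ndarray) -> None:
        self._hist.append(np.asarray(task_losses, dtype=float))

    @property
    def ready(self) -> bool:
        return len(self._hist) >= 2

    def sigmas(self) -> np.ndarray:
        arr = np.stack(self._hist)
        return np.maximum(arr.std(axis=0, ddof=1), self.floor)

    def weights(self) -> np.ndarray:
        if not self.ready:
            return np.ones(3)
        lam = uncertainty_weights(self.sigmas())
        return lam / lam.mean()
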