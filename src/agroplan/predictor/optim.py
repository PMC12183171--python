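"""AdamW with global-norm gradient clipping.

The update keeps exponential moving averages of the gradient (m) and its
square (v) and steps theta <- theta - eta * m_hat / (sqrt(v_hat) + eps), with
weight decay applied directly (decoupled) to the parameters.  Bias correction
(the hats) is on by default; ``bias_correction=False`` gives the raw
moment-ratio update for strict replication of the plain printed rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..autodiff import Tensor

__all__ = ["OptimizerState", "AdamW", "clip_gradients"]


def clip_gradients(grads: dict[str, np.ndarray], clip_norm: float | None,
                   ) -> tuple[dict[str, np.ndarray], float]:
    """Scale the whole gradient so its global L2 norm is at most ``clip_norm``.

    Returns the (possibly scaled) gradients and the pre-clip global norm.
    """
    gnorm = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
    if clip_norm is None or gnorm <= clip_norm or gnorm == 0.0:
        return grads, gnorm
    scale = clip_norm / gnorm
    return {k: g * scale for k, g in grads.items()}, gnorm


@dataclass
class OptimizerState:
    """Moments and counters for one optimized parameter set."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-2
    clip_norm: float | None = 1.0
    bias_correction: bool = True
    step_count: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {self.lr}")
        if self.eps <= 0:
            raise ValueError(f"numerical guard eps must be > 0, got {self.eps}")


class AdamW:
    """Decoupled-weight-decay adaptive optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], **kwargs):
        self.params = params
        self.state = OptimizerState(**kwargs)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self, grads: dict[str, np.ndarray] | None = None) -> float:
        """Apply one update from ``grads`` (default: the recorded ``.grad``s).

        Refuses the step (raises) on non-finite gradients.  Returns the
        pre-clip global gradient norm.
        """
        st = self.state
        if grads is None:
            grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                     for k, p in self.params.items()}
        for k, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for parameter {k!r}")
        grads, gnorm = clip_gradients(grads, st.clip_norm)

        st.step_count += 1
        t = st.step_count
        for k, p in self.params.items():
            g = np.asarray(grads[k], dtype=float)
            m = st.m.setdefault(k, np.zeros_like(p.data))
            v = st.v.setdefault(k, np.zeros_like(p.data))
            m *= st.beta1
            m += (1 - st.beta1) * g
            v *= st.beta2
            v += (1 - st.beta2) * g**2
            if st.bias_correction:
                m_hat = m / (1 - st.beta1**t)
                v_hat = v / (1 - st.beta2**t)
            else:
                m_hat, v_hat = m, v
            if st.weight_decay:
                p.data -= st.lr * st.weight_decay * p.data
            p.data -= st.lr * m_hat / (np.sqrt(v_hat) + st.eps)
        return gnorm
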