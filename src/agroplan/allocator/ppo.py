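"""Clipped-surrogate policy optimization over the farm environment.

The policy is a diagonal Gaussian over the normalized action box [0, 1]^n_u:
a two-layer tanh network maps state features to the mean (through a sigmoid)
and a global log-standard-deviation vector is learned alongside.  Sampled
actions are clipped to the box and rescaled to physical doses; emitted doses
are additionally capped by the remaining budget during rollouts, so every
executed plan is feasible.

Losses follow the standard clipped-surrogate recipe: probability ratios
r_t = pi_theta / pi_theta_old at the stored actions, the pessimistic
min(r A, clip(r, 1-eps, 1+eps) A) policy term, a squared-error value term,
and an entropy bonus.  The total is assembled in minimization convention:
total = -policy_term + c1 * value_term - c2 * entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..autodiff import Tensor, as_tensor, minimum
from ..predictor.layers import _init

__all__ = ["td_error", "gae", "entropy_bonus", "gaussian_entropy",
           "GaussianPolicy", "ValueNet", "PpoConfig", "ppo_losses",
           "select_action_ci"]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# scalar identities
# ---------------------------------------------------------------------------

def td_error(reward: float, gamma: float, v_next: float, v_now: float) -> float:
    """One-step temporal-difference error  delta = R + gamma*V(s') - V(s).

    Terminal steps use the convention V(s') = 0 (pass ``v_next=0``).
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"discount gamma must lie in (0, 1], got {gamma}")
    return float(reward) + gamma * float(v_next) - float(v_now)


def gae(rewards: np.ndarray, values: np.ndarray, gamma: float,
        lam: float) -> np.ndarray:
    """Generalized advantage estimates by the backward recursion.

    ``values`` has length T+1 (bootstrap value appended); the result equals
    the explicit double sum  A_t = sum_{l>=0} (gamma*lam)^l delta_{t+l}
    exactly.  ``lam = 0`` reduces to the one-step TD error.
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    t_len = len(rewards)
    if len(values) != t_len + 1:
        raise ValueError(
            f"values must have length T+1={t_len + 1}, got {len(values)}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"GAE decay must lie in [0, 1], got {lam}")
    deltas = rewards + gamma * values[1:] - values[:-1]
    adv = np.empty(t_len)
    acc = 0.0
    for t in range(t_len - 1, -1, -1):
        acc = deltas[t] + gamma * lam * acc
        adv[t] = acc
    return adv


def entropy_bonus(probs: np.ndarray, beta: float) -> float:
    """Entropy bonus  -beta * sum_a pi(a) log pi(a)  for a discrete policy.

    Requires a normalized distribution; maximal at uniform (log K for K
    actions, with beta = 1).
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("probs must be a normalized distribution")
    nz = p[p > 0]
    return float(-beta * np.sum(nz * np.log(nz)))


def gaussian_entropy(log_std: np.ndarray) -> float:
    """Closed-form entropy of a diagonal Gaussian: sum_d [0.5*log(2*pi*e) + log sigma_d]."""
    ls = np.asarray(log_std, dtype=float)
    return float(np.sum(0.5 * (_LOG_2PI + 1.0) + ls))


# ---------------------------------------------------------------------------
# policy / value networks
# ---------------------------------------------------------------------------

class GaussianPolicy:
    """Diagonal Gaussian policy over the normalized action box [0, 1]^n_u."""

    def __init__(self, state_dim: int, action_dim: int, hidden: int = 32,
                 init_log_std: float = -1.0, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = _init(rng, state_dim, hidden)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = _init(rng, hidden, action_dim)
        self.b2 = Tensor(np.zeros(action_dim), requires_grad=True)
        self.log_std = Tensor(np.full(action_dim, init_log_std),
                              requires_grad=True)
        self.action_dim = action_dim

    def parameters(self) -> dict[str, Tensor]:
        return {"pi.w1": self.w1, "pi.b1": self.b1, "pi.w2": self.w2,
                "pi.b2": self.b2, "pi.log_std": self.log_std}

    def mean(self, features: np.ndarray | Tensor) -> Tensor:
        """Policy mean in [0, 1]^n_u for a batch of state features."""
        x = as_tensor(features)
        hidden = (x @ self.w1 + self.b1).tanh()
        return (hidden @ self.w2 + self.b2).sigmoid()

    def log_prob(self, features, actions) -> Tensor:
        """Log-density of raw (pre-clip) normalized actions, batched."""
        mu = self.mean(features)
        a = as_tensor(actions)
        z = (a - mu) * (-self.log_std).exp()
        return (z * z * -0.5 - self.log_std
                - 0.5 * _LOG_2PI).sum(axis=-1)

    def sample(self, features: np.ndarray, rng: np.random.Generator,
               deterministic: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Draw raw normalized actions and their log-probs (numpy, no graph)."""
        mu = self.mean(features).numpy()
        if deterministic:
            raw = mu.copy()
        else:
            std = np.exp(self.log_std.data)
            raw = mu + std * rng.standard_normal(mu.shape)
        lp = self.log_prob(features, raw).numpy()
        return raw, lp

    def entropy(self) -> float:
        return gaussian_entropy(self.log_std.data)

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.parameters().items():
            p.data = np.asarray(state[k], dtype=float).copy()


class ValueNet:
    """Two-layer state-value estimator V(s)."""

    def __init__(self, state_dim: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed + 1000)
        self.w1 = _init(rng, state_dim, hidden)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = _init(rng, hidden, 1)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        return {"v.w1": self.w1, "v.b1": self.b1, "v.w2": self.w2,
                "v.b2": self.b2}

    def forward(self, features) -> Tensor:
        x = as_tensor(features)
        hidden = (x @ self.w1 + self.b1).tanh()
        return (hidden @ self.w2 + self.b2).reshape(-1)

    def values(self, features: np.ndarray) -> np.ndarray:
        return self.forward(features).numpy()

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.parameters().items():
            p.data = np.asarray(state[k], dtype=float).copy()


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PpoConfig:
    """Standard clipped-surrogate hyperparameters."""

    gamma: float = 0.99
    lam_gae: float = 0.95
    clip_eps: float = 0.2
    c1: float = 0.5              # value-loss weight
    c2: float = 0.01             # entropy weight
    surrogate_epochs: int = 4
    lr: float = 3e-3
    anchor_weight: float = 0.0   # lambda on ||u - u0||^2 through the policy mean
    risk_alpha: float = 0.0      # mean - alpha*var action selection overlay

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not 0.0 <= self.lam_gae <= 1.0:
            raise ValueError("lam_gae must lie in [0, 1]")
        if self.clip_eps <= 0:
            raise ValueError("clip_eps must be > 0")
        if min(self.c1, self.c2, self.anchor_weight) < 0:
            raise ValueError("c1, c2 and anchor_weight must be >= 0")


@dataclass
class PpoLossParts:
    total: Tensor
    policy_term: float
    value_term: float
    entropy_term: float
    ratios: np.ndarray


def ppo_losses(policy: GaussianPolicy, value_net: ValueNet,
               features: np.ndarray, actions: np.ndarray,
               old_log_probs: np.ndarray, advantages: np.ndarray,
               value_targets: np.ndarray, cfg: PpoConfig,
               anchor: np.ndarray | None = None) -> PpoLossParts:
    """Assemble the clipped-surrogate total loss on one batch.

    ``old_log_probs`` must be the log-densities recorded under the frozen
    snapshot when the actions were sampled — at theta = theta_old all ratios
    are exactly 1.  ``anchor``, when given, is the (batch, n_u) normalized
    warm-start plan; its squared deviation from the policy mean joins the
    total with weight ``cfg.anchor_weight``.
    """
    if old_log_probs is None:
        raise ValueError("stored old log-probabilities are required")
    adv = np.asarray(advantages, dtype=float)
    lp = policy.log_prob(features, actions)
    ratios = (lp - np.asarray(old_log_probs)).exp()

    surr = minimum(ratios * adv,
                   ratios.clip(1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps) * adv)
    policy_term = surr.mean()                       # maximized

    v = value_net.forward(features)
    vdiff = v - np.asarray(value_targets, dtype=float)
    value_term = (vdiff * vdiff).mean()

    # differentiable Gaussian entropy (depends only on log_std)
    ent = (0.5 * (_LOG_2PI + 1.0) + policy.log_std).sum()

    total = (policy_term * -1.0) + cfg.c1 * value_term - cfg.c2 * ent
    if anchor is not None and cfg.anchor_weight > 0:
        mu = policy.mean(features)
        dev = mu - np.asarray(anchor, dtype=float)
        total = total + cfg.anchor_weight * (dev * dev).mean()

    return PpoLossParts(total=total,
                        policy_term=float(policy_term.item()),
                        value_term=float(value_term.item()),
                        entropy_term=float(ent.item()),
                        ratios=ratios.numpy())


# ---------------------------------------------------------------------------
# risk-aware action selection
# ---------------------------------------------------------------------------

def select_action_ci(candidates: np.ndarray, reward_samples: list[np.ndarray],
                     risk_alpha: float) -> tuple[int, np.ndarray]:
    """Pick argmax_k [mean(R_k) - alpha * var(R_k)] over candidate actions.

    ``reward_samples[k]`` holds >= 2 Monte-Carlo reward draws for candidate
    ``k`` (unbiased sample variance); ties resolve to the lowest index.
    Returns (chosen index, per-candidate scores).
    """
    if len(reward_samples) != len(candidates) or len(candidates) == 0:
        raise ValueError("need one non-empty sample set per candidate")
    scores = np.empty(len(candidates))
    for k, samples in enumerate(reward_samples):
        s = np.asarray(samples, dtype=float)
        if s.size < 2:
            raise ValueError(f"candidate {k} needs >= 2 reward samples")
        scores[k] = s.mean() - risk_alpha * s.var(ddof=1)
    return int(np.argmax(scores)), scores
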