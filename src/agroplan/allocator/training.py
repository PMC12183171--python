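"""Training loop for the resource-allocation policy.

Each field is an independent episode of the same MDP (one shared policy):
the state is the field condition plus the previous action, the action is the
per-step dose vector, and the reward is a1*Y - a2*C - a3*E.  Emitted doses
are clipped to the agronomic box and capped by the remaining season budget,
so every executed action satisfies the constraint checker by construction.

An iteration collects a batch of seasons, computes advantages with GAE,
then runs several clipped-surrogate epochs over the batch.  The optional
anchored feedback adds a penalty pulling the policy mean toward the
warm-start plan at the visited states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .. import simulator as sim
from ..predictor.optim import AdamW
from .ppo import GaussianPolicy, PpoConfig, ValueNet, gae, ppo_losses

__all__ = ["PolicyState", "TrainPolicyConfig", "train_policy", "eval_policy",
           "collect_rollouts", "feedback_update"]


@dataclass
class PolicyState:
    """Actor/critic parameters plus the frozen snapshot and anchor plan."""

    policy: GaussianPolicy
    value_net: ValueNet
    config: PpoConfig
    anchor_plan: np.ndarray | None = None       # (m, T, n_u) physical doses
    old_snapshot: dict[str, np.ndarray] | None = None

    def snapshot(self) -> None:
        self.old_snapshot = self.policy.get_state()


@dataclass(frozen=True)
class TrainPolicyConfig:
    iterations: int = 30
    episodes_per_iter: int = 8     # seasons collected per iteration (all fields)
    minibatch_size: int = 128
    hidden: int = 32
    weights: sim.ObjectiveWeights = field(default_factory=sim.ObjectiveWeights)
    reward_scale: float = 1e-2     # keeps advantages O(1) for the toy env


def _feature_dim(env: sim.EnvironmentParams) -> int:
    s = sim.baseline_state(env)
    return sim.state_features(s, env).size


def _emit_dose(env: sim.EnvironmentParams, raw: np.ndarray,
               remaining_budget: float) -> np.ndarray:
    """Normalized raw action -> feasible physical dose."""
    upper = np.asarray(env.dose_upper, dtype=float)
    lower = np.asarray(env.dose_lower, dtype=float)
    dose = np.clip(raw, 0.0, 1.0) * upper
    dose = np.clip(dose, lower, upper)
    total = dose.sum()
    if total > remaining_budget:
        dose = dose * (max(remaining_budget, 0.0) / max(total, 1e-12))
    return dose


@dataclass
class RolloutBatch:
    features: np.ndarray        # (N, d_s)
    raw_actions: np.ndarray     # (N, n_u) normalized, pre-clip
    doses: np.ndarray           # (N, n_u) physical, feasible
    log_probs: np.ndarray       # (N,)
    advantages: np.ndarray      # (N,)
    value_targets: np.ndarray   # (N,)
    episode_returns: np.ndarray  # (episodes * m,)
    anchor: np.ndarray | None = None   # (N, n_u) normalized warm-start doses


def collect_rollouts(env: sim.EnvironmentParams, state: PolicyState,
                     n_episodes: int, rng: np.random.Generator,
                     weights: sim.ObjectiveWeights,
                     reward_scale: float = 1e-2) -> RolloutBatch:
    """Run seasons under the current policy and assemble a GAE-ready batch."""
    cfg = state.config
    upper = np.asarray(env.dose_upper, dtype=float)
    feats, raws, doses, lps, advs, vtargs, rets = [], [], [], [], [], [], []
    anchors = [] if state.anchor_plan is not None else None

    for _ep in range(n_episodes):
        inits = sim.initial_states(env, rng)
        for i, s0 in enumerate(inits):
            s = s0.copy()
            prev = np.zeros(env.n_actions)
            remaining = env.budget / env.n_fields
            ep_feats, ep_raw, ep_dose, ep_lp, ep_rew = [], [], [], [], []
            for t in range(env.horizon):
                f = sim.state_features(s, env, prev)
                raw, lp = state.policy.sample(f[None, :], rng)
                dose = _emit_dose(env, raw[0], remaining)
                remaining -= dose.sum()
                out = sim.outcome(env, s, dose)
                r = sim.reward(out, weights) * reward_scale
                ep_feats.append(f)
                ep_raw.append(raw[0])
                ep_dose.append(dose)
                ep_lp.append(lp[0])
                ep_rew.append(r)
                if anchors is not None:
                    anchors.append(state.anchor_plan[i, t] / upper)
                s = sim.step(env, s, dose, rng)
                prev = dose
            ep_feats = np.asarray(ep_feats)
            values = state.value_net.values(ep_feats)
            values = np.append(values, 0.0)       # terminal bootstrap
            adv = gae(np.asarray(ep_rew), values, cfg.gamma, cfg.lam_gae)
            vt = adv + values[:-1]
            feats.append(ep_feats)
            raws.append(np.asarray(ep_raw))
            doses.append(np.asarray(ep_dose))
            lps.append(np.asarray(ep_lp))
            advs.append(adv)
            vtargs.append(vt)
            rets.append(float(np.sum(ep_rew)) / reward_scale)

    return RolloutBatch(
        features=np.concatenate(feats),
        raw_actions=np.concatenate(raws),
        doses=np.concatenate(doses),
        log_probs=np.concatenate(lps),
        advantages=np.concatenate(advs),
        value_targets=np.concatenate(vtargs),
        episode_returns=np.asarray(rets),
        anchor=np.asarray(anchors) if anchors is not None else None,
    )


def feedback_update(state: PolicyState, batch: RolloutBatch,
                    optimizer: AdamW, rng: np.random.Generator,
                    minibatch_size: int = 128) -> dict[str, float]:
    """Several surrogate epochs on one batch, with the optional anchor term.

    With ``anchor_weight = 0`` (or no anchor plan) this is exactly the plain
    clipped-surrogate update.
    """
    cfg = state.config
    n = len(batch.features)
    adv = batch.advantages
    adv = (adv - adv.mean()) / max(adv.std(), 1e-8)
    stats = {"policy": 0.0, "value": 0.0, "entropy": 0.0}
    count = 0
    for _epoch in range(cfg.surrogate_epochs):
        order = rng.permutation(n)
        for start in range(0, n, minibatch_size):
            idx = order[start:start + minibatch_size]
            anchor = (batch.anchor[idx]
                      if batch.anchor is not None and cfg.anchor_weight > 0
                      else None)
            parts = ppo_losses(
                state.policy, state.value_net, batch.features[idx],
                batch.raw_actions[idx], batch.log_probs[idx], adv[idx],
                batch.value_targets[idx], cfg, anchor=anchor)
            optimizer.zero_grad()
            parts.total.backward()
            optimizer.step()
            stats["policy"] += parts.policy_term
            stats["value"] += parts.value_term
            stats["entropy"] += parts.entropy_term
            count += 1
    return {k: v / max(count, 1) for k, v in stats.items()}


def train_policy(env: sim.EnvironmentParams, seed: int = 0,
                 ppo_config: PpoConfig | None = None,
                 train_config: TrainPolicyConfig | None = None,
                 anchor_plan: np.ndarray | None = None,
                 ) -> tuple[PolicyState, list[dict[str, float]]]:
    """Full training loop; fully reproducible under a fixed seed.

    Returns the trained :class:`PolicyState` and a per-iteration history of
    mean return and loss components.
    """
    cfg = ppo_config or PpoConfig()
    tc = train_config or TrainPolicyConfig()
    rng = np.random.default_rng(seed)
    d = _feature_dim(env)
    state = PolicyState(
        policy=GaussianPolicy(d, env.n_actions, hidden=tc.hidden, seed=seed),
        value_net=ValueNet(d, hidden=tc.hidden, seed=seed),
        config=cfg,
        anchor_plan=anchor_plan,
    )
    params = {**state.policy.parameters(), **state.value_net.parameters()}
    opt = AdamW(params, lr=cfg.lr, weight_decay=0.0, clip_norm=0.5)

    history: list[dict[str, float]] = []
    for it in range(tc.iterations):
        state.snapshot()
        batch = collect_rollouts(env, state, tc.episodes_per_iter, rng,
                                 tc.weights, tc.reward_scale)
        stats = feedback_update(state, batch, opt, rng, tc.minibatch_size)
        history.append({"iteration": it,
                        "mean_return": float(batch.episode_returns.mean()),
                        **stats})
    return state, history


def eval_policy(env: sim.EnvironmentParams, state: PolicyState,
                n_episodes: int, seed: int = 0,
                weights: sim.ObjectiveWeights | None = None,
                deterministic: bool = True) -> tuple[float, np.ndarray]:
    """Mean episode return (physical reward units) over evaluation seasons.

    All emitted actions are feasibility-capped exactly as in training; the
    per-episode dose trajectories are returned for constraint auditing.
    """
    weights = weights or sim.ObjectiveWeights()
    rng = np.random.default_rng(seed)
    returns = []
    all_doses = []
    for _ep in range(n_episodes):
        inits = sim.initial_states(env, rng)
        total = 0.0
        for i, s0 in enumerate(inits):
            s = s0.copy()
            prev = np.zeros(env.n_actions)
            remaining = env.budget / env.n_fields
            for t in range(env.horizon):
                f = sim.state_features(s, env, prev)
                raw, _ = state.policy.sample(f[None, :], rng,
                                             deterministic=deterministic)
                dose = _emit_dose(env, raw[0], remaining)
                remaining -= dose.sum()
                all_doses.append(dose)
                total += sim.reward(sim.outcome(env, s, dose), weights)
                s = sim.step(env, s, dose, rng)
                prev = dose
        returns.append(total)
    return float(np.mean(returns)), np.asarray(all_doses)
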