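"""Policy-optimization identities: TD error, GAE, ratios, entropy, training."""

import numpy as np
import pytest

import agroplan as ap
from agroplan import simulator as sim
from agroplan.allocator import (GaussianPolicy, PolicyState, PpoConfig,
                                ValueNet, entropy_bonus, gae,
                                gaussian_entropy, ppo_losses,
                                select_action_ci, td_error)
from agroplan.allocator.training import (TrainPolicyConfig, collect_rollouts,
                                         eval_policy, feedback_update,
                                         train_policy)
from agroplan.predictor.optim import AdamW


def gae_double_sum(rewards, values, gamma, lam):
    """Explicit double-sum definition of the advantage estimates."""
    t_len = len(rewards)
    deltas = [rewards[t] + gamma * values[t + 1] - values[t]
              for t in range(t_len)]
    return np.array([
        sum((gamma * lam) ** l * deltas[t + l] for l in range(t_len - t))
        for t in range(t_len)])


class TestTdAndGae:
    def test_td_error_arithmetic(self):
        assert td_error(1.0, 0.9, 2.0, 1.0) == pytest.approx(1.8)

    def test_terminal_convention(self):
        assert td_error(2.5, 0.99, 0.0, 1.0) == pytest.approx(1.5)

    def test_td_random_tuples_match_formula(self, rng):
        for _ in range(50):
            r, vn, v = rng.standard_normal(3)
            g = rng.uniform(0.01, 1.0)
            assert td_error(r, g, vn, v) == r + g * vn - v

    def test_gae_lambda_zero_is_td_error(self, rng):
        rewards = rng.standard_normal(6)
        values = rng.standard_normal(7)
        adv = gae(rewards, values, 0.9, 0.0)
        deltas = rewards + 0.9 * values[1:] - values[:-1]
        assert np.array_equal(adv, deltas)

    def test_hand_telescoped_example(self):
        adv = gae([1.0, 1.0], [0.0, 0.0, 0.0], 1.0, 1.0)
        assert np.allclose(adv, [2.0, 1.0])

    def test_recursion_equals_double_sum(self, rng):
        for _ in range(20):
            t_len = rng.integers(1, 12)
            rewards = rng.standard_normal(t_len)
            values = rng.standard_normal(t_len + 1)
            g = rng.uniform(0.1, 1.0)
            lam = rng.uniform(0.0, 1.0)
            assert np.max(np.abs(gae(rewards, values, g, lam)
                                 - gae_double_sum(rewards, values, g, lam))) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="T\\+1"):
            gae([1.0, 2.0], [0.0, 0.0], 0.9, 0.9)


class TestEntropy:
    def test_uniform_four_actions(self):
        assert entropy_bonus(np.full(4, 0.25), 1.0) == pytest.approx(
            np.log(4), abs=1e-12)

    def test_one_hot_zero_entropy(self):
        assert entropy_bonus(np.array([0.0, 1.0, 0.0]), 1.0) == 0.0

    def test_random_distributions_match_summation(self, rng):
        for _ in range(20):
            p = rng.random(5)
            p /= p.sum()
            beta = rng.random() * 2
            want = -beta * sum(pi * np.log(pi) for pi in p if pi > 0)
            assert entropy_bonus(p, beta) == pytest.approx(want, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            entropy_bonus(np.array([0.5, 0.2]), 1.0)

    def test_gaussian_closed_form(self):
        ls = np.array([0.0, np.log(2.0)])
        want = 2 * 0.5 * np.log(2 * np.pi * np.e) + 0.0 + np.log(2.0)
        assert gaussian_entropy(ls) == pytest.approx(want, abs=1e-12)


def make_batch(rng, n=16, d=5, a=2):
    policy = GaussianPolicy(d, a, hidden=8, seed=3)
    vnet = ValueNet(d, hidden=8, seed=3)
    feats = rng.standard_normal((n, d))
    raw, lp = policy.sample(feats, rng)
    return policy, vnet, feats, raw, lp


class TestPpoLosses:
    def test_ratios_exactly_one_at_old_parameters(self, rng):
        """At theta = theta_old every probability ratio is exactly 1 and the
        surrogate equals the mean advantage."""
        policy, vnet, feats, raw, lp = make_batch(rng)
        adv = rng.standard_normal(len(feats))
        parts = ppo_losses(policy, vnet, feats, raw, lp, adv,
                           np.zeros(len(feats)), PpoConfig())
        assert np.all(parts.ratios == 1.0)
        assert parts.policy_term == pytest.approx(adv.mean(), abs=1e-12)

    def test_clip_arithmetic_factor(self):
        """Ratio 2 with eps 0.2 and positive advantage: the clipped branch
        contributes factor 1.2 and the min picks it."""
        eps, adv, ratio = 0.2, 1.5, 2.0
        clipped = np.clip(ratio, 1 - eps, 1 + eps) * adv
        assert clipped == pytest.approx(1.2 * adv)
        assert min(ratio * adv, clipped) == clipped

    def test_losses_match_hand_enumeration(self, rng):
        """Total/parts agree with a direct transition-by-transition
        re-computation of the clipped surrogate, value and entropy terms."""
        policy, vnet, feats, raw, lp_old = make_batch(rng, n=8)
        # perturb parameters so ratios differ from 1
        for p in policy.parameters().values():
            p.data += 0.05 * rng.standard_normal(p.shape)
        adv = rng.standard_normal(8)
        vt = rng.standard_normal(8)
        cfg = PpoConfig(clip_eps=0.2, c1=0.5, c2=0.01)
        parts = ppo_losses(policy, vnet, feats, raw, lp_old, adv, vt, cfg)

        lp_new = policy.log_prob(feats, raw).numpy()
        ratios = np.exp(lp_new - lp_old)
        surr = np.minimum(ratios * adv,
                          np.clip(ratios, 0.8, 1.2) * adv).mean()
        v = vnet.values(feats)
        vloss = ((v - vt) ** 2).mean()
        ent = gaussian_entropy(policy.log_std.data)
        want_total = -surr + cfg.c1 * vloss - cfg.c2 * ent
        assert parts.total.item() == pytest.approx(want_total, abs=1e-10)
        assert parts.policy_term == pytest.approx(surr, abs=1e-10)
        assert parts.value_term == pytest.approx(vloss, abs=1e-10)
        assert parts.entropy_term == pytest.approx(ent, abs=1e-10)

    def test_missing_old_log_probs_rejected(self, rng):
        policy, vnet, feats, raw, _ = make_batch(rng)
        with pytest.raises(ValueError, match="log-probabilities"):
            ppo_losses(policy, vnet, feats, raw, None,
                       np.zeros(len(feats)), np.zeros(len(feats)), PpoConfig())


class TestAnchoredFeedback:
    def test_zero_anchor_weight_identical_to_plain_step(self, env_toy, rng):
        """anchor_weight = 0 reproduces the plain update bit for bit."""
        d = sim.state_features(sim.baseline_state(env_toy), env_toy).size
        results = []
        for anchor_w in (0.0, 0.0):
            cfg = PpoConfig(anchor_weight=anchor_w)
            state = PolicyState(
                policy=GaussianPolicy(d, 2, hidden=8, seed=5),
                value_net=ValueNet(d, hidden=8, seed=5), config=cfg,
                anchor_plan=np.zeros((env_toy.n_fields, env_toy.horizon, 2)))
            params = {**state.policy.parameters(),
                      **state.value_net.parameters()}
            opt = AdamW(params, lr=1e-3, weight_decay=0.0)
            r = np.random.default_rng(0)
            batch = collect_rollouts(env_toy, state, 2, r,
                                     sim.ObjectiveWeights())
            feedback_update(state, batch, opt, np.random.default_rng(1))
            results.append(state.policy.get_state())
        for k in results[0]:
            assert np.array_equal(results[0][k], results[1][k])

    def test_anchor_gradient_zero_at_anchor(self, rng):
        """When the policy mean equals the anchor, the anchor term adds no
        gradient."""
        policy = GaussianPolicy(4, 2, hidden=8, seed=0)
        vnet = ValueNet(4, hidden=8, seed=0)
        feats = rng.standard_normal((6, 4))
        raw, lp = policy.sample(feats, rng)
        anchor = policy.mean(feats).numpy()   # anchor == current mean
        cfg0 = PpoConfig(anchor_weight=0.0)
        cfg1 = PpoConfig(anchor_weight=10.0)
        g = {}
        for tag, cfg in (("off", cfg0), ("on", cfg1)):
            parts = ppo_losses(policy, vnet, feats, raw, lp,
                               np.ones(6), np.zeros(6), cfg,
                               anchor=anchor if cfg.anchor_weight else None)
            for p in policy.parameters().values():
                p.zero_grad()
            for p in vnet.parameters().values():
                p.zero_grad()
            parts.total.backward()
            g[tag] = {k: (p.grad.copy() if p.grad is not None else 0)
                      for k, p in policy.parameters().items()}
        for k in g["off"]:
            assert np.allclose(g["off"][k], g["on"][k], atol=1e-10)

    def test_anchor_gradient_matches_finite_differences(self, rng):
        """d/dtheta of anchor_weight * mean||mu(s) - u0||^2 checks against
        central differences."""
        policy = GaussianPolicy(3, 2, hidden=6, seed=1)
        feats = rng.standard_normal((5, 3))
        anchor = rng.random((5, 2))
        lam = 3.0

        def penalty():
            mu = policy.mean(feats)
            d = mu - anchor
            return lam * (d * d).mean()

        loss = penalty()
        for p in policy.parameters().values():
            p.zero_grad()
        loss.backward()
        h = 1e-6
        for name, p in policy.parameters().items():
            if name == "pi.log_std":
                continue
            flat = p.data.ravel()
            gflat = p.grad.ravel()
            for j in rng.choice(flat.size, min(3, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + h
                fp = penalty().item()
                flat[j] = orig - h
                fm = penalty().item()
                flat[j] = orig
                num = (fp - fm) / (2 * h)
                assert abs(num - gflat[j]) / max(abs(num), abs(gflat[j]), 1e-8) < 1e-6


class TestSelectActionCi:
    def test_risk_neutral_is_mean_argmax(self, rng):
        samples = [rng.normal(m, 1.0, 50) for m in (0.0, 2.0, 1.0)]
        k, _ = select_action_ci(np.arange(3), samples, 0.0)
        assert k == int(np.argmax([s.mean() for s in samples]))

    def test_variance_penalty_prefers_low_variance(self):
        a = np.array([1.0, 3.0])      # mean 2, var 2
        b = np.array([-1.0, 5.0])     # mean 2, var 18
        k, scores = select_action_ci(np.arange(2), [a, b], 0.5)
        assert k == 0
        assert scores[0] == pytest.approx(2 - 0.5 * 2.0)

    def test_tie_resolves_to_lowest_index(self):
        s = np.array([1.0, 3.0])
        k, _ = select_action_ci(np.arange(3), [s, s.copy(), s.copy()], 0.3)
        assert k == 0

    def test_matches_exhaustive_scoring(self, rng):
        for _ in range(10):
            n = rng.integers(2, 7)
            samples = [rng.standard_normal(rng.integers(2, 20)) for _ in range(n)]
            alpha = rng.random()
            k, _ = select_action_ci(np.arange(n), samples, alpha)
            brute = [s.mean() - alpha * s.var(ddof=1) for s in samples]
            assert k == int(np.argmax(brute))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            select_action_ci(np.arange(2), [np.array([1.0, 2.0]),
                                            np.array([1.0])], 0.1)


class TestTrainPolicy:
    def test_seed_matched_runs_identical(self, env_toy):
        tc = TrainPolicyConfig(iterations=3, episodes_per_iter=2)
        _, h1 = train_policy(env_toy, seed=7, train_config=tc)
        _, h2 = train_policy(env_toy, seed=7, train_config=tc)
        assert [x["mean_return"] for x in h1] == [x["mean_return"] for x in h2]

    def test_all_emitted_actions_feasible(self, env_toy):
        tc = TrainPolicyConfig(iterations=4, episodes_per_iter=4)
        state, _ = train_policy(env_toy, seed=3, train_config=tc)
        _, doses = eval_policy(env_toy, state, 10, seed=11)
        per_field = env_toy.horizon
        plan = sim.ControlPlan.zeros(env_toy)
        # audit each evaluation season as its own plan
        for e in range(len(doses) // per_field):
            plan.actions = doses[e * per_field:(e + 1) * per_field][None]
            rep = ap.check_constraints(plan)
            assert rep.budget.satisfied and rep.agronomic.satisfied

    def test_training_improves_over_initial_policy(self, env_toy):
        """On the noiseless 1-field toy environment the trained policy beats
        the untrained one (majority over 3 seeds)."""
        wins = 0
        for seed in (0, 1, 2):
            tc = TrainPolicyConfig(iterations=20, episodes_per_iter=8)
            trained, _ = train_policy(env_toy, seed=seed, train_config=tc)
            init, _ = train_policy(env_toy, seed=seed,
                                   train_config=TrainPolicyConfig(iterations=0))
            r_trained, _ = eval_policy(env_toy, trained, 30, seed=100 + seed)
            r_init, _ = eval_policy(env_toy, init, 30, seed=100 + seed)
            wins += int(r_trained > r_init)
        assert wins >= 2

    def test_yield_only_objective_recovers_known_optimal_dose(self, env_toy):
        """With alpha = (1, 0, 0) and a generous budget the learned mean
        water dose moves toward the simulator's known yield-optimal constant
        dose (found by grid search on the noiseless rollout).

        Because over-irrigation drives soil moisture past the crop's optimum
        and depresses health, the yield-optimal dose sits below saturation —
        a property of the documented transition model, which the policy must
        discover."""
        import dataclasses
        env = dataclasses.replace(env_toy, budget=1e9)
        w = sim.ObjectiveWeights(1.0, 0.0, 0.0)

        # known optimum: best constant water dose, fertilizer at saturation
        def season_yield(dw):
            plan = sim.ControlPlan.zeros(env)
            plan.actions[:] = [dw, env.saturation_dose[1]]
            init = [sim.baseline_state(env, 0)]
            traj = sim.rollout(env, plan, np.random.default_rng(0), init=init)
            return sim.objective(traj.outcomes, w)

        grid = np.linspace(0, env.dose_upper[0], 61)
        dose_star = grid[int(np.argmax([season_yield(g) for g in grid]))]

        tc = TrainPolicyConfig(iterations=30, episodes_per_iter=8, weights=w)
        state, _ = train_policy(env, seed=1, train_config=tc)
        _, doses = eval_policy(env, state, 10, seed=5, weights=w)
        init_state, _ = train_policy(env, seed=1,
                                     train_config=TrainPolicyConfig(
                                         iterations=0, weights=w))
        _, doses0 = eval_policy(env, init_state, 10, seed=5, weights=w)
        gap = abs(doses[:, 0].mean() - dose_star)
        gap0 = abs(doses0[:, 0].mean() - dose_star)
        assert gap < gap0
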