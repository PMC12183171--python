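"""Baselines, metrics, Shapley attribution, economics and the weight sweep."""

import numpy as np
import pandas as pd
import pytest

import agroplan as ap
from agroplan import evaluate as ev
from agroplan import simulator as sim


class TestRuleBasedPolicy:
    def test_fires_when_dry(self, env_default):
        s = sim.baseline_state(env_default)
        s.soil_moisture = 0.2
        a = ev.rule_based_policy(s, env_default)
        assert a[sim.WATER] == ev.RuleThresholds().irrigation_dose

    def test_silent_when_wet(self, env_default):
        s = sim.baseline_state(env_default)
        s.soil_moisture = 0.9
        assert ev.rule_based_policy(s, env_default)[sim.WATER] == 0.0

    def test_deterministic(self, env_default):
        s = sim.baseline_state(env_default)
        s.soil_moisture = 0.3
        a1 = ev.rule_based_policy(s, env_default)
        a2 = ev.rule_based_policy(s, env_default)
        assert np.array_equal(a1, a2)

    def test_fertilizer_follows_schedule(self, env_default):
        th = ev.RuleThresholds()
        s = sim.baseline_state(env_default)
        s.resources[sim.FERT] = 0.0
        assert ev.rule_based_policy(s, env_default)[sim.FERT] == th.fert_dose
        s.resources[sim.FERT] = th.fert_season_target
        assert ev.rule_based_policy(s, env_default)[sim.FERT] == 0.0


class TestGreedyPolicy:
    def test_returns_known_one_step_optimum(self, env_noiseless):
        s = sim.baseline_state(env_noiseless)
        grid = ev.default_candidate_grid(env_noiseless, n=4)
        best = ev.greedy_policy(s, env_noiseless, grid)
        w = sim.ObjectiveWeights()
        rewards = [sim.reward(sim.outcome(env_noiseless, s, a), w) for a in grid]
        assert np.array_equal(best, grid[int(np.argmax(rewards))])

    def test_singleton_grid(self, env_noiseless):
        s = sim.baseline_state(env_noiseless)
        only = np.array([[123.0, 4.0]])
        assert np.array_equal(ev.greedy_policy(s, env_noiseless, only), only[0])

    def test_tie_resolves_to_smallest_dose(self, env_noiseless):
        """Above saturation the yield is flat; with zero cost/impact weights,
        equal-reward candidates tie and the smallest dose wins."""
        s = sim.baseline_state(env_noiseless)
        sat = np.asarray(env_noiseless.saturation_dose)
        cands = np.stack([sat, 1.5 * sat])
        w = sim.ObjectiveWeights(1.0, 0.0, 0.0)
        got = ev.greedy_policy(s, env_noiseless, cands, weights=w)
        assert np.array_equal(got, sat)

    def test_empty_grid_rejected(self, env_noiseless):
        s = sim.baseline_state(env_noiseless)
        with pytest.raises(ValueError, match="non-empty"):
            ev.greedy_policy(s, env_noiseless, np.zeros((0, 2)))


class TestCompareStrategies:
    def strategies(self, env):
        grid = ev.default_candidate_grid(env, n=3)
        return {
            "rule": lambda s, e: ev.rule_based_policy(s, e),
            "greedy": lambda s, e: ev.greedy_policy(s, e, grid),
            "max-dose": lambda s, e: np.asarray(e.dose_upper, dtype=float),
        }

    def test_same_seed_identical_report(self, env_default):
        strats = self.strategies(env_default)
        r1 = ev.compare_strategies(env_default, strats, episodes=3, seed=5,
                                   adaptability=False)
        r2 = ev.compare_strategies(env_default, strats, episodes=3, seed=5,
                                   adaptability=False)
        # latency is wall-clock and informational only; all data columns match
        cols = [c for c in r1.columns if "latency" not in c]
        pd.testing.assert_frame_equal(r1[cols], r2[cols])

    def test_wasteful_strategy_uses_more_resources(self, env_default):
        rep = ev.compare_strategies(env_default, self.strategies(env_default),
                                    episodes=4, seed=2, adaptability=False)
        rep = rep.set_index("strategy")
        assert rep.loc["max-dose", "water_mean"] >= rep.loc["rule", "water_mean"]
        assert rep.loc["max-dose", "fert_mean"] >= rep.loc["rule", "fert_mean"]

    def test_single_episode_matches_direct_rollout(self, env_noiseless):
        """A 1-episode, 1-strategy report equals an independent rollout."""
        th = ev.RuleThresholds()
        strat = {"rule": lambda s, e: ev.rule_based_policy(s, e, th)}
        rep = ev.compare_strategies(env_noiseless, strat, episodes=1, seed=9,
                                    adaptability=False)
        rng = np.random.default_rng(9)
        traj = sim.rollout(env_noiseless,
                           lambda s: ev.rule_based_policy(s, env_noiseless, th),
                           rng=rng)
        want_yield = traj.outcome_array()[:, :, 0].sum() / env_noiseless.n_fields
        assert rep["yield_mean"].iloc[0] == pytest.approx(want_yield, rel=1e-12)

    def test_adaptability_proxy_reported(self, env_default):
        rep = ev.compare_strategies(env_default, self.strategies(env_default),
                                    episodes=2, seed=0, adaptability=True)
        assert "adaptability" in rep.columns
        assert rep["adaptability"].notna().all()


class TestClassificationMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = ev.classification_metrics(y, s)
        assert m == {"accuracy": 1.0, "recall": 1.0, "f1": 1.0, "auc": 1.0}

    def test_auc_matches_pairwise_count_oracle(self, rng):
        for _ in range(15):
            y = rng.integers(0, 2, 40)
            if y.sum() in (0, 40):
                y[0] = 1 - y[0]
            s = np.round(rng.random(40), 1)   # force ties
            auc = ev.classification_metrics(y, s)["auc"]
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_label_permutation_null_auc_half(self, rng):
        """Scores independent of labels give mean AUC ~ 0.5 across
        permutations."""
        s = rng.random(60)
        y = np.array([0, 1] * 30)
        aucs = []
        for _ in range(200):
            yp = rng.permutation(y)
            aucs.append(ev.classification_metrics(yp, s)["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            ev.classification_metrics(np.ones(5), np.random.rand(5))


class TestShapley:
    def test_constant_predictor_all_zero(self, rng):
        f = lambda X: np.full(len(np.atleast_2d(X)), 7.0)
        res = ev.shapley_attribution(f, rng.random(4), rng.random((10, 4)),
                                     n_samples=50, seed=0)
        assert np.allclose(res.values, 0.0, atol=1e-12)
        assert res.efficiency_residual < 1e-12

    def test_linear_model_matches_closed_form(self, rng):
        """For f(x) = w.x the Shapley value is phi_j = w_j (x_j - mean b_j)."""
        w = np.array([2.0, -1.0, 0.5, 3.0])
        f = lambda X: np.atleast_2d(X) @ w
        x = rng.random(4)
        bg = rng.random((20, 4))
        res = ev.shapley_attribution(f, x, bg, n_samples=2000, seed=1)
        want = w * (x - bg.mean(axis=0))
        rel = np.abs(res.values - want) / np.maximum(np.abs(want), 1e-9)
        assert np.max(rel) < 0.05

    def test_matches_exact_coalition_enumeration(self, rng):
        """3-feature nonlinear model vs exact Shapley over all 2^3 coalitions
        (single background row, so the exact value is well-defined)."""
        def f(X):
            X = np.atleast_2d(X)
            return X[:, 0] * X[:, 1] + np.sin(X[:, 2]) + 0.5 * X[:, 0]

        x = rng.random(3)
        b = rng.random(3)
        import itertools
        import math
        exact = np.zeros(3)
        for j in range(3):
            others = [k for k in range(3) if k != j]
            for r in range(3):
                for s_set in itertools.combinations(others, r):
                    weight = (math.factorial(r)
                              * math.factorial(3 - r - 1) / math.factorial(3))
                    z = b.copy()
                    z[list(s_set)] = x[list(s_set)]
                    without = f(z[None])[0]
                    z[j] = x[j]
                    with_j = f(z[None])[0]
                    exact[j] += weight * (with_j - without)

        res = ev.shapley_attribution(f, x, b[None, :], n_samples=4000, seed=2)
        # Monte-Carlo standard error of each phi_j is well under 0.05 here
        assert np.max(np.abs(res.values - exact)) < 0.05

    def test_efficiency_residual_shrinks_with_samples(self, rng):
        w = rng.standard_normal(5)
        f = lambda X: np.atleast_2d(X) @ w
        x, bg = rng.random(5), rng.random((15, 5))
        res_small = ev.shapley_attribution(f, x, bg, n_samples=20, seed=3)
        res_big = ev.shapley_attribution(f, x, bg, n_samples=2000, seed=3)
        assert res_big.efficiency_residual <= res_small.efficiency_residual + 1e-9

    def test_failing_predictor_propagates_with_context(self, rng):
        def boom(X):
            raise RuntimeError("sensor offline")

        with pytest.raises(RuntimeError, match="attribution"):
            ev.shapley_attribution(boom, rng.random(3), rng.random((4, 3)),
                                   n_samples=5, seed=0)


class TestCostBenefit:
    def test_twenty_percent_reduction(self):
        r = ev.cost_benefit(500.0, 0.20, 100.0, 0.10)
        assert r["per_ha_saving"] == 100.0
        assert r["total_saving"] == 10_000.0

    def test_twenty_five_percent_reduction(self):
        r = ev.cost_benefit(500.0, 0.25, 100.0, 0.15)
        assert r["per_ha_saving"] == 125.0
        assert r["total_saving"] == 12_500.0

    def test_zero_reduction_zero_savings(self):
        r = ev.cost_benefit(500.0, 0.0, 100.0)
        assert r["per_ha_saving"] == 0.0 and r["total_saving"] == 0.0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ev.cost_benefit(500.0, 1.2, 100.0)
        with pytest.raises(ValueError, match="area"):
            ev.cost_benefit(500.0, 0.2, 0.0)


class TestSensitivitySweep:
    def test_same_seed_identical_surface(self, env_toy):
        grid = np.array([[1.0, 0.0, 0.0], [0.4, 0.3, 0.3]])
        t1 = ev.sensitivity_sweep(env_toy, grid, episodes_per_cell=2, seed=3,
                                  train_iterations=2, episodes_per_iter=2)
        t2 = ev.sensitivity_sweep(env_toy, grid, episodes_per_cell=2, seed=3,
                                  train_iterations=2, episodes_per_iter=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_rows_normalized_to_simplex(self, env_toy):
        t = ev.sensitivity_sweep(env_toy, np.array([[2.0, 1.0, 1.0]]),
                                 episodes_per_cell=1, seed=0,
                                 train_iterations=1, episodes_per_iter=2)
        assert t[["alpha1", "alpha2", "alpha3"]].iloc[0].sum() == pytest.approx(1.0)

    def test_negative_weights_rejected(self, env_toy):
        with pytest.raises(ValueError, match="non-negative"):
            ev.sensitivity_sweep(env_toy, np.array([[1.0, -0.1, 0.1]]))

    def test_yield_weighted_cell_outyields_cost_weighted_cell(self, env_toy):
        """alpha = (1,0,0) trains toward yield; alpha = (0,1,0) toward cost
        avoidance (doing nothing), so its raw yield is lower — majority over
        3 seeds."""
        grid = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        wins = 0
        for seed in (0, 1, 2):
            t = ev.sensitivity_sweep(env_toy, grid, episodes_per_cell=3,
                                     seed=seed, train_iterations=30,
                                     episodes_per_iter=8)
            wins += int(t["yield_mean"].iloc[0] >= t["yield_mean"].iloc[1])
        assert wins >= 2
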