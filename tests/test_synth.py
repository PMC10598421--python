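import numpy as np
import pytest
from scipy.stats import ks_2samp

from marronoid import synth, treeio
from marronoid.mk import RateModel
from marronoid.synth import (TrajectoryConfig, simulate_continuous,
                             simulate_discrete, simulate_regression_dataset,
                             simulate_trajectory, simulate_tree)


class TestTreeSim:
    def test_two_tips_is_cherry(self):
        t = simulate_tree(2, 1.0, 0.0, seed=1)
        assert t.n_tips == 2
        assert t.blen[0] == pytest.approx(t.blen[1])

    def test_tip_count_and_bifurcation(self):
        t = simulate_tree(50, 1.0, 0.0, seed=2)
        assert t.n_tips == 50
        assert t.n_nodes == 99          # 49 internal nodes when bifurcating
        assert t.is_ultrametric
        assert np.all(t.blen[np.arange(t.n_nodes) != t.root] > 0)

    def test_with_extinction_still_conditioned(self):
        t = simulate_tree(30, 1.0, 0.6, seed=3)
        assert t.n_tips == 30
        assert t.is_ultrametric

    def test_seed_determinism(self):
        a = treeio.write_newick(simulate_tree(20, 1.0, 0.2, seed=7))
        b = treeio.write_newick(simulate_tree(20, 1.0, 0.2, seed=7))
        assert a == b

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_tree(5, 0.5, 0.5, seed=0)


class TestDiscreteSim:
    def test_zero_rates_no_events(self, six_tip_tree):
        h = simulate_discrete(six_tip_tree, RateModel(0.0, 0.0), seed=1,
                              root_state=0)
        assert all(s == 0 for s in h.tip_states.values())
        assert h.n_events == 0

    def test_dollo_never_gains(self):
        t = simulate_tree(100, 1.0, 0.0, seed=5)
        h = simulate_discrete(t, RateModel(0.0, 0.5), seed=6, root_state=1)
        assert h.n_gain == 0

    def test_event_count_matches_poisson_expectation(self):
        # oracle: under ER the exit rate is q from either state, so the
        # number of events is Poisson with mean q x total branch length
        t = simulate_tree(200, 1.0, 0.0, seed=8)
        q = 0.5
        tot = t.total_branch_length
        counts = [simulate_discrete(t, RateModel(q, q, constraint="ER"),
                                    seed=s).n_events for s in range(30)]
        mean_expect = q * tot
        se = np.sqrt(mean_expect / 30)
        assert abs(np.mean(counts) - mean_expect) < 4 * se

    def test_determinism(self, six_tip_tree):
        a = simulate_discrete(six_tip_tree, RateModel(0.3, 0.6), seed=9)
        b = simulate_discrete(six_tip_tree, RateModel(0.3, 0.6), seed=9)
        assert a.tip_states == b.tip_states and a.events == b.events


class TestContinuousSim:
    def test_zero_variance_constant(self, six_tip_tree):
        y = simulate_continuous(six_tip_tree, "BM", {"sigma2": 0.0, "z0": 7.0},
                                seed=1)
        assert np.allclose(y, 7.0)

    def test_bm_star_tree_variance(self):
        # oracle: BM variance at depth t is sigma2 * t
        star = treeio.read_newick("(" + ",".join(
            f"t{i}:2" for i in range(2000)) + ");")
        y = simulate_continuous(star, "BM", {"sigma2": 1.5, "z0": 0.0}, seed=2)
        assert np.var(y) == pytest.approx(3.0, rel=0.05)

    def test_lambda_zero_equals_star_distribution(self):
        # oracle: lambda = 0 covariance is the star construction
        t = simulate_tree(1000, 1.0, 0.0, seed=3)
        t.blen *= 2.0 / t.tree_height
        t._depths = None
        y_lam = simulate_continuous(t, "lambda",
                                    {"sigma2": 1.0, "z0": 0.0, "lambda": 0.0},
                                    seed=4)
        rng = np.random.default_rng(5)
        y_star = rng.normal(0, np.sqrt(2.0), 1000)
        assert ks_2samp(y_lam, y_star).pvalue > 0.01

    def test_replicate_covariance_matches_model(self, six_tip_tree):
        reps = simulate_continuous(six_tip_tree, "lambda",
                                   {"sigma2": 2.0, "z0": 1.0, "lambda": 0.6},
                                   seed=6, size=5000)
        C = treeio.lambda_cov(treeio.vcv(six_tip_tree), 0.6) * 2.0
        S = np.cov(reps.T)
        # sd of a sample-covariance entry here is ~sqrt(72/5000) ~ 0.12;
        # allow 3 MC standard errors on top of the 10% relative band
        assert np.allclose(S, C, rtol=0.10, atol=0.36)


class TestRegressionSim:
    def test_group_shift_construction(self, six_tip_tree):
        g = np.array([0, 0, 0, 1, 1, 1])
        df = simulate_regression_dataset(six_tip_tree, g, beta=10.0,
                                         params={"sigma2": 1e-6}, seed=1)
        diff = df[df.group == 1].y.mean() - df[df.group == 0].y.mean()
        assert diff == pytest.approx(10.0, abs=0.05)

    def test_null_has_no_shift_in_expectation(self, six_tip_tree):
        g = np.array([0, 1, 0, 1, 0, 1])
        diffs = [simulate_regression_dataset(
            six_tip_tree, g, beta=0.0, params={"sigma2": 1.0}, seed=s
        ).pipe(lambda d: d[d.group == 1].y.mean() - d[d.group == 0].y.mean())
            for s in range(200)]
        assert abs(np.mean(diffs)) < 0.25


class TestTrajectorySim:
    def test_noise_free_constant_velocity(self):
        cfg = TrajectoryConfig(seed=1, profile="constant", osc_amplitude_bl=0.0,
                               jitter_px=0.0, v_max_cm_s=30.0)
        traj, vtrue = simulate_trajectory(cfg)
        d = np.hypot(np.diff(traj.x_px), np.diff(traj.y_px))
        assert np.allclose(d, 30.0 / cfg.fps * cfg.px_per_cm, atol=1e-9)
        assert np.allclose(vtrue, 30.0)

    def test_determinism(self):
        a, _ = simulate_trajectory(TrajectoryConfig(seed=4))
        b, _ = simulate_trajectory(TrajectoryConfig(seed=4))
        assert np.array_equal(a.x_px, b.x_px) and np.array_equal(a.y_px, b.y_px)

    def test_metadata_embedded(self):
        cfg = TrajectoryConfig(seed=2, fps=250.0, px_per_cm=40.0,
                               body_length_cm=0.8)
        traj, _ = simulate_trajectory(cfg)
        assert traj.fps == 250.0 and traj.px_per_cm == 40.0
        assert traj.body_length_cm == 0.8

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            simulate_trajectory(TrajectoryConfig(seed=0, duration_s=0.01,
                                                 fps=100.0))


class TestRecoveryThroughPipeline:
    def test_regression_beta_coverage(self):
        # the simulation is its own oracle: the fitted CI should cover the
        # generating beta in a large majority of replicates
        from marronoid.pgls import group_contrast_report, phylo_lm
        tree = simulate_tree(100, 1.0, 0.0, seed=10)
        rng = np.random.default_rng(11)
        g = rng.integers(0, 2, 100).astype(float)
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            df = simulate_regression_dataset(
                tree, g, beta=5.0, model="lambda",
                params={"sigma2": 1.0, "lambda": 0.7}, seed=100 + s)
            fit = phylo_lm(tree, df["y"].to_numpy(), g, method="lambda",
                           names=["grp"])
            rep = group_contrast_report(fit, "grp")
            hits += rep["ci_low"] <= 5.0 <= rep["ci_high"]
        assert hits >= int(0.85 * n_rep)
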