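import numpy as np
import pytest

from conftest import enumerate_mk_likelihood, random_small_tree

from marronoid import synth, treeio
from marronoid.infocrit import aicc_weights
from marronoid.mk import (MkFit, RateModel, ancestral_posteriors, fit_mk,
                          mk_loglik, sample_maps, summarize_maps,
                          transition_probs)

EQ = np.array([0.5, 0.5])


class TestLoglik:
    def test_cherry_closed_form(self, cherry):
        # hand computation: L = P00(1) P01(1) + P10(1) P11(1) over equal root
        # prior with ER q=0.5: (0.5+0.5e^-1)(0.5-0.5e^-1) ~ 0.21617
        ll = mk_loglik(cherry, {"A": 0, "B": 1}, RateModel(0.5, 0.5, constraint="ER"))
        assert np.exp(ll) == pytest.approx(0.21617, abs=1e-5)

    def test_no_change_possible(self, three_tip_tree):
        mod = RateModel(0.0, 0.0)
        ll = mk_loglik(three_tip_tree, {"A": 0, "B": 0, "C": 0}, mod)
        assert ll == pytest.approx(np.log(0.5))

    def test_impossible_data_gives_minus_inf(self, three_tip_tree):
        mod = RateModel(0.0, 0.0)
        assert mk_loglik(three_tip_tree, {"A": 0, "B": 1, "C": 0}, mod) == -np.inf

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            t = random_small_tree(rng)
            q01, q10 = rng.uniform(0.05, 2.0, 2)
            mod = RateModel(q01, q10)
            tips = {lab: int(rng.integers(2)) for lab in t.tip_labels}
            expect = enumerate_mk_likelihood(t, tips, mod.Q, mod.pi)
            got = np.exp(mk_loglik(t, tips, mod))
            assert got == pytest.approx(expect, abs=1e-10)

    def test_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            P = transition_probs(rng.uniform(0, 5), rng.uniform(0, 5),
                                 rng.uniform(0, 10, size=7))
            assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)

    def test_unknown_tip_label_raises(self, cherry):
        with pytest.raises(KeyError):
            mk_loglik(cherry, {"A": 0, "Z": 1}, RateModel(0.1, 0.1))


class TestFit:
    def test_dollo_gain_rate_is_zero(self, six_tip_tree):
        tips = {l: s for l, s in zip(six_tip_tree.tip_labels, [1, 1, 0, 1, 0, 1])}
        fit = fit_mk(six_tip_tree, tips, "DOLLO")
        assert fit.model.q01 == 0.0
        assert fit.model.pi[1] == 1.0     # root fixed web-present

    def test_er_nested_in_ard(self):
        tree = synth.simulate_tree(40, 1.0, 0.0, seed=11)
        h = synth.simulate_discrete(tree, RateModel(0.4, 0.4, constraint="ER"),
                                    seed=12)
        er = fit_mk(tree, h.tip_states, "ER")
        ard = fit_mk(tree, h.tip_states, "ARD", seed=0)
        assert er.loglik <= ard.loglik + 1e-6
        assert er.k_free == 1 and ard.k_free == 2

    def test_er_rate_recovery_single(self):
        tree = synth.simulate_tree(300, 1.0, 0.0, seed=21)
        tree.blen *= 5.0 / tree.tree_height
        tree._depths = None
        h = synth.simulate_discrete(tree, RateModel(0.3, 0.3, constraint="ER"),
                                    seed=22)
        fit = fit_mk(tree, h.tip_states, "ER")
        assert 0.1 < fit.model.q01 < 0.9

    def test_aicc_formula(self, six_tip_tree):
        tips = {l: s for l, s in zip(six_tip_tree.tip_labels, [1, 0, 0, 1, 0, 1])}
        fit = fit_mk(six_tip_tree, tips, "ER")
        k, n = 1, 6
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1))


class TestWeights:
    def test_equal_aicc_splits_evenly(self):
        assert np.allclose(aicc_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two(self):
        # oracle: direct evaluation of w = exp(-d/2)/sum
        w = aicc_weights([0.0, 2.0])
        e = np.exp(-1.0)
        assert np.allclose(w, [1 / (1 + e), e / (1 + e)])
        assert w[0] == pytest.approx(0.731, abs=5e-4)

    def test_sum_to_one(self):
        rng = np.random.default_rng(3)
        w = aicc_weights(rng.uniform(0, 50, 6))
        assert w.sum() == pytest.approx(1.0)


class TestAncestralPosteriors:
    def test_all_same_state_no_rates(self, six_tip_tree):
        tips = {l: 1 for l in six_tip_tree.tip_labels}
        post = ancestral_posteriors(six_tip_tree, tips, RateModel(1e-8, 1e-8))
        assert np.allclose(post[:, 1], 1.0, atol=1e-4)

    def test_symmetric_cherry_root(self, cherry):
        post = ancestral_posteriors(cherry, {"A": 0, "B": 1},
                                    RateModel(0.5, 0.5, constraint="ER"))
        assert post[cherry.root] == pytest.approx([0.5, 0.5])

    def test_matches_enumeration(self):
        # oracle: node-marginal = sum of enumerated joint likelihoods with
        # that node's state clamped, normalized
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = random_small_tree(rng)
            mod = RateModel(*rng.uniform(0.05, 1.5, 2))
            tips = {lab: int(rng.integers(2)) for lab in t.tip_labels}
            total = enumerate_mk_likelihood(t, tips, mod.Q, mod.pi)
            if total <= 0:
                continue
            post = ancestral_posteriors(t, tips, mod)
            for v in range(t.n_tips, t.n_nodes):
                clamped = [_enumerate_with_clamp(t, tips, mod, v, s)
                           for s in (0, 1)]
                expect = np.array(clamped) / total
                assert np.allclose(post[v], expect, atol=1e-10)


def _enumerate_with_clamp(tree, tips, mod, node, state):
    import itertools

    from scipy.linalg import expm
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    P = {v: expm(mod.Q * tree.blen[v]) for v in range(tree.n_nodes)
         if v != tree.root}
    tip_state = {tree.tip_index[lab]: s for lab, s in tips.items()}
    total = 0.0
    for assign in itertools.product(range(2), repeat=len(internals)):
        st = dict(zip(internals, assign))
        if st[node] != state:
            continue
        st.update(tip_state)
        lik = mod.pi[st[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                lik *= P[v][st[tree.parent[v]], st[v]]
        total += lik
    return total


class TestSampleMaps:
    def test_near_zero_rates_no_events(self, six_tip_tree):
        tips = {l: 1 for l in six_tip_tree.tip_labels}
        maps = sample_maps(six_tip_tree, tips, RateModel(1e-8, 1e-8),
                           n_maps=50, seed=1)
        s = summarize_maps(maps)
        assert s["mean_gains"] + s["mean_losses"] < 0.01

    def test_dollo_maps_never_gain(self, six_tip_tree):
        tips = {l: s for l, s in zip(six_tip_tree.tip_labels, [1, 1, 0, 1, 0, 0])}
        fit = fit_mk(six_tip_tree, tips, "DOLLO")
        maps = sample_maps(six_tip_tree, tips, fit.model, n_maps=300, seed=2)
        assert all(m.n_gain == 0 for m in maps)
        assert sum(m.n_loss for m in maps) > 0

    def test_events_consistent_with_endpoints(self, six_tip_tree):
        tips = {l: s for l, s in zip(six_tip_tree.tip_labels, [1, 0, 0, 1, 0, 1])}
        mod = RateModel(0.4, 0.6)
        for m in sample_maps(six_tip_tree, tips, mod, n_maps=100, seed=3):
            for v, evs in m.events.items():
                state = m.node_states[six_tip_tree.parent[v]]
                last_t = 0.0
                for t, a, b in evs:
                    assert a == state and 0 <= t <= six_tip_tree.blen[v]
                    assert t >= last_t
                    state, last_t = b, t
                assert state == m.node_states[v]

    def test_node_frequencies_match_posteriors(self, six_tip_tree):
        tips = {l: s for l, s in zip(six_tip_tree.tip_labels, [1, 0, 0, 1, 0, 1])}
        mod = RateModel(0.35, 0.55)
        post = ancestral_posteriors(six_tip_tree, tips, mod)
        maps = sample_maps(six_tip_tree, tips, mod, n_maps=4000, seed=4)
        freq = np.mean([m.node_states for m in maps], axis=0)
        assert np.allclose(freq[six_tip_tree.n_tips:],
                           post[six_tip_tree.n_tips:, 1], atol=0.03)

    def test_mean_counts_match_forward_simulation(self):
        # matched-conditions check: forward histories vs conditioned maps
        tree = synth.simulate_tree(80, 1.0, 0.0, seed=31)
        tree.blen *= 4.0 / tree.tree_height
        tree._depths = None
        mod = RateModel(0.3, 0.3, constraint="ER")
        fwd_losses, map_losses = [], []
        for seed in range(30):
            h = synth.simulate_discrete(tree, mod, seed=seed)
            fwd_losses.append(h.n_loss + h.n_gain)
            maps = sample_maps(tree, h.tip_states, mod, n_maps=20, seed=seed)
            s = summarize_maps(maps)
            map_losses.append(s["mean_losses"] + s["mean_gains"])
        fwd, mp = np.mean(fwd_losses), np.mean(map_losses)
        se = np.std(fwd_losses, ddof=1) / np.sqrt(30) + \
            np.std(map_losses, ddof=1) / np.sqrt(30)
        assert abs(fwd - mp) <= 3 * se + 0.5
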