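import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

from karyosocial import mk_simmap
from karyosocial.mk_simmap import (
    build_rate_matrix,
    fit_mk,
    mk_loglik,
    sample_branch_path,
    sample_histories,
    sample_histories_for_data,
    simmap_to_annotated_newick,
    state_occupancy,
    transition_probability,
)
from karyosocial.phylo_core import Phylogeny

from conftest import random_tree
from oracles import mk_loglik_enumeration


def two_state_q(gain, loss):
    return build_rate_matrix([gain, loss], 2, "ARD")


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        Q = two_state_q(0.7, 0.3)
        assert np.allclose(transition_probability(Q, 0.0), np.eye(2))

    @pytest.mark.parametrize("q,t", [(0.5, 0.3), (2.0, 1.7)])
    def test_symmetric_closed_form(self, q, t):
        Q = two_state_q(q, q)
        P = transition_probability(Q, t)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-2 * q * t),
                                        abs=1e-12)

    def test_long_time_reaches_stationary(self):
        rng = np.random.default_rng(3)
        rates = rng.uniform(0.5, 2.0, size=12)
        Q = build_rate_matrix(rates, 4, "ARD")
        # stationary distribution from the eigen-decomposition (left null
        # vector of Q), an independent route
        w, vl = np.linalg.eig(Q.T)
        pi = np.real(vl[:, np.argmin(np.abs(w))])
        pi = pi / pi.sum()
        P = transition_probability(Q, 1e6 / np.abs(Q).max())
        for row in P:
            np.testing.assert_allclose(row, pi, atol=1e-6)

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            transition_probability(two_state_q(1, 1), -0.1)

    def test_rows_are_distributions(self):
        Q = build_rate_matrix(np.random.default_rng(0).uniform(0, 3, 12),
                              4, "ARD")
        P = transition_probability(Q, 0.37)
        assert np.all(P >= 0) and np.all(P <= 1)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestMkLoglik:
    def test_two_tip_closed_form(self):
        tree = Phylogeny.from_newick("(A:0.4,B:0.4);")
        Q = two_state_q(0.9, 0.4)
        P = transition_probability(Q, 0.4)
        ll = mk_loglik(tree, {"A": 0, "B": 1}, Q, root_state=0)
        assert ll == pytest.approx(np.log(P[0, 0] * P[0, 1]), abs=1e-12)

    def test_zero_rates_all_root_state(self, balanced_tree):
        Q = np.zeros((2, 2))
        ll = mk_loglik(balanced_tree, {lb: 0 for lb in
                                       balanced_tree.tip_labels}, Q, 0)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_missing_tip_state_errors(self, balanced_tree):
        with pytest.raises(ValueError, match="without a state"):
            mk_loglik(balanced_tree, {"A": 0}, two_state_q(1, 1), 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_equals_enumeration(self, seed):
        """Felsenstein pruning against summation over all internal states."""
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 7))
        tree = random_tree(rng, n_tips)
        k = int(rng.integers(2, 4))
        Q = build_rate_matrix(rng.uniform(0.1, 2.0, k * (k - 1)), k, "ARD")
        states = rng.integers(0, k, size=tree.n_tips)
        ll = mk_loglik(tree, states, Q, root_state=0)
        assert ll == pytest.approx(
            mk_loglik_enumeration(tree, states, Q, 0), abs=1e-10)


class TestFitMk:
    def test_degenerate_data_rates_at_floor(self, balanced_tree):
        states = {lb: 0 for lb in balanced_tree.tip_labels}
        fit = fit_mk(balanced_tree, states, root_state=0, n_restarts=2)
        assert fit.loglik == pytest.approx(0.0, abs=1e-4)

    def test_equal_rates_nested_in_ard(self, small_dataset):
        tree = small_dataset.tree
        states = np.array([small_dataset.truth["tip_states"][lb]
                           for lb in tree.tip_labels])
        ard = fit_mk(tree, states, 0, "ARD", n_restarts=3)
        er = fit_mk(tree, states, 0, "ER", n_restarts=3)
        assert er.loglik <= ard.loglik + 1e-6

    def test_fit_beats_arbitrary_matrices(self, small_dataset):
        tree = small_dataset.tree
        states = np.array([small_dataset.truth["tip_states"][lb]
                           for lb in tree.tip_labels])
        fit = fit_mk(tree, states, 0, n_restarts=3)
        rng = np.random.default_rng(1)
        for _ in range(5):
            Q = two_state_q(*rng.uniform(0.05, 5.0, 2))
            assert fit.loglik >= mk_loglik(tree, states, Q, 0) - 1e-6


class TestSampleHistories:
    def test_zero_rate_single_segment(self, balanced_tree):
        Q = np.zeros((2, 2))
        maps = sample_histories_for_data(
            balanced_tree, np.zeros(4, dtype=int), Q, 0, n_maps=3, seed=1)
        for m in maps:
            assert np.all(m.node_states == 0)
            for segs in m.segments[1:]:
                assert len(segs) == 1

    def test_branch_durations_conserved(self, small_dataset):
        tree = small_dataset.tree
        states = np.array([small_dataset.truth["tip_states"][lb]
                           for lb in tree.tip_labels])
        Q = two_state_q(1.0, 0.5)
        maps = sample_histories_for_data(tree, states, Q, 0, n_maps=3, seed=2)
        for m in maps:
            for i in range(1, tree.n_nodes):
                assert m.branch_duration(i) == pytest.approx(
                    float(tree.edge_length[i]), abs=1e-9)

    def test_segment_endpoints_match_node_states(self, small_dataset):
        tree = small_dataset.tree
        states = np.array([small_dataset.truth["tip_states"][lb]
                           for lb in tree.tip_labels])
        maps = sample_histories_for_data(tree, states, two_state_q(1.0, 0.5),
                                         0, n_maps=2, seed=3)
        for m in maps:
            assert m.node_states[0] == 0  # fixed root
            for i in range(1, tree.n_nodes):
                segs = m.segments[i]
                assert segs[0][0] == m.node_states[tree.parent[i]]
                assert segs[-1][0] == m.node_states[i]
                for (s1, _), (s2, _) in zip(segs, segs[1:]):
                    assert s1 != s2
            tips = m.node_states[tree.tip_indices]
            assert np.array_equal(tips, states)

    def test_reproducible_by_seed(self, small_dataset):
        tree = small_dataset.tree
        states = np.array([small_dataset.truth["tip_states"][lb]
                           for lb in tree.tip_labels])
        Q = two_state_q(1.0, 0.5)
        a = sample_histories_for_data(tree, states, Q, 0, 2, seed=9)
        b = sample_histories_for_data(tree, states, Q, 0, 2, seed=9)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.node_states, mb.node_states)
            assert ma.segments == mb.segments

    def test_occupancy_conserves_total_length(self, small_dataset):
        tree = small_dataset.tree
        states = np.array([small_dataset.truth["tip_states"][lb]
                           for lb in tree.tip_labels])
        maps = sample_histories_for_data(tree, states, two_state_q(1.0, 0.5),
                                         0, n_maps=2, seed=4)
        for m in maps:
            occ = state_occupancy(m)
            assert sum(occ.values()) == pytest.approx(
                tree.total_branch_length, abs=1e-9)

    def test_impossible_endpoints_error(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        Q = np.zeros((2, 2))
        with pytest.raises(ValueError, match="probability|branch"):
            sample_histories_for_data(tree, np.array([0, 1]), Q, 0, 1, seed=0)

    def test_annotated_newick_mentions_every_branch(self, balanced_tree):
        maps = sample_histories_for_data(
            balanced_tree, np.array([0, 1, 0, 1]), two_state_q(1.0, 0.5),
            0, 1, seed=5)
        text = simmap_to_annotated_newick(maps[0])
        assert text.count("[&map=") == balanced_tree.n_nodes - 1


class TestBranchPathDistribution:
    def test_expected_dwell_time_matches_quadrature(self):
        """Mean occupancy of the derived state on one endpoint-conditioned
        branch equals the analytic expectation
        integral P_0j(s) P_j1(t-s) ds / P_01(t)."""
        Q = two_state_q(0.8, 0.5)
        t, a, b = 1.3, 0, 1
        P_t = transition_probability(Q, t)

        def integrand(s):
            return (transition_probability(Q, s)[a, 1]
                    * transition_probability(Q, t - s)[1, b])

        expected = quad(integrand, 0, t)[0] / P_t[a, b]
        rng = np.random.default_rng(12345)
        n = 10_000
        dwell = np.empty(n)
        for i in range(n):
            segs = sample_branch_path(Q, t, a, b, rng, p_ab=P_t[a, b])
            dwell[i] = sum(d for s, d in segs if s == 1)
        se = dwell.std(ddof=1) / np.sqrt(n)
        assert abs(dwell.mean() - expected) < 3 * se

    def test_exchangeability_across_seed_batches(self):
        """Dwell-time distributions from two seed batches are
        indistinguishable (KS test)."""
        Q = two_state_q(0.8, 0.5)
        P_t = transition_probability(Q, 1.0)

        def batch(seed, n=4000):
            rng = np.random.default_rng(seed)
            return np.array([
                sum(d for s, d in sample_branch_path(Q, 1.0, 0, 1, rng,
                                                     p_ab=P_t[0, 1]) if s == 1)
                for _ in range(n)])

        p = ks_2samp(batch(1), batch(2)).pvalue
        assert p > 0.01

    def test_zero_length_branch(self):
        Q = two_state_q(1.0, 1.0)
        assert sample_branch_path(Q, 0.0, 1, 1,
                                  np.random.default_rng(0)) == [(1, 0.0)]
        with pytest.raises(ValueError):
            sample_branch_path(Q, 0.0, 0, 1, np.random.default_rng(0))
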