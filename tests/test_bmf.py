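import itertools

import numpy as np
import pytest

import helpers
from bmfcluster.bmf import (
    BMFModel,
    FitConfig,
    fit,
    fit_multi,
    harmony,
    init_factorization,
    model_selection_step,
    model_to_biclusters,
    model_to_clusters,
    reconstruction,
    yang_step,
    ying_step,
)
from bmfcluster.graph_io import ComplexSet
from bmfcluster.synthetic_data import complexes_to_graph, generate_planted_complexes


def _sym_model(assign, m, eps=0.01, kappa=1.0, alpha=None):
    assign = np.asarray(assign)
    if alpha is None:
        counts = np.bincount(assign, minlength=m)
        alpha = (counts + kappa) / (assign.size + m * kappa)
    return BMFModel(item_assign=assign, alpha=np.asarray(alpha, dtype=float),
                    eps=eps, kappa=kappa, m=m, symmetric=True)


class TestInit:
    def test_single_cluster_forced(self):
        x = np.zeros((3, 3))
        model = init_factorization(x, FitConfig(m_init=1, seed=0))
        assert model.m == 1 and model.alpha.tolist() == [1.0]
        assert (model.item_assign == 0).all()

    def test_deterministic(self, two_clique_graph):
        cfg = FitConfig(m_init=5, seed=123)
        a = init_factorization(two_clique_graph, cfg)
        b = init_factorization(two_clique_graph, cfg)
        assert (a.item_assign == b.item_assign).all() and a.eps == b.eps

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            init_factorization(np.full((3, 3), 0.5), FitConfig(m_init=2))

    def test_asymmetric_rejected_in_symmetric_mode(self):
        x = np.zeros((3, 3))
        x[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            init_factorization(x, FitConfig(m_init=2, symmetric=True))

    def test_overparameterized_init_prunes_to_item_count(self):
        cs = generate_planted_complexes(20, (5, 5), seed=0)
        x = complexes_to_graph(cs).adjacency  # 100 items
        model = init_factorization(x, FitConfig(m_init=300, seed=4))
        pruned = model_selection_step(model)
        assert pruned.m <= 100


class TestReconstruction:
    def test_block_diagonal(self):
        model = _sym_model([0, 0, 1], m=2)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        assert (reconstruction(model) == expected).all()

    def test_single_cluster_all_ones(self):
        model = _sym_model([0, 0, 0], m=1)
        assert (reconstruction(model) == 1).all()

    def test_boolean_equals_clipped_integer_product(self):
        for assign in itertools.product(range(3), repeat=3):
            model = _sym_model(list(assign), m=3)
            integer = np.minimum(model.A @ model.Y, 1)
            assert (reconstruction(model) == integer).all()


class TestHarmony:
    def test_invariant_under_relabeling(self, two_clique_graph):
        a = _sym_model([0, 0, 1, 1], m=2)
        b = _sym_model([1, 1, 0, 0], m=2)
        assert harmony(two_clique_graph, a) == pytest.approx(harmony(two_clique_graph, b))

    def test_half_eps_closed_form(self, two_clique_graph):
        model = _sym_model([0, 0, 1, 1], m=2, eps=0.5)
        pair_term = 6 * np.log(0.5)  # C(4,2) pairs regardless of assignment
        expected = np.log(model.alpha[model.item_assign]).sum() + pair_term
        assert harmony(two_clique_graph, model) == pytest.approx(expected)

    def test_true_partition_maximizes_over_enumeration(self, two_clique_graph):
        best_h = -np.inf
        best_assign = None
        for assign in itertools.product(range(2), repeat=4):
            h = helpers.brute_harmony_symmetric(two_clique_graph, assign)
            if h > best_h:
                best_h, best_assign = h, assign
        groups = [frozenset(np.flatnonzero(np.array(best_assign) == j).tolist())
                  for j in set(best_assign)]
        assert sorted(groups, key=min) == [frozenset({0, 1}), frozenset({2, 3})]

    def test_agrees_with_brute_force(self, two_clique_graph):
        for assign in itertools.product(range(2), repeat=4):
            model = ying_step(two_clique_graph.astype(float),
                              _sym_model(list(assign), m=2))
            model = model_selection_step(model)
            assert harmony(two_clique_graph, model) == pytest.approx(
                helpers.brute_harmony_symmetric(two_clique_graph, assign), abs=1e-9
            )

    def test_zero_probability_assignment_rejected(self, two_clique_graph):
        model = _sym_model([0, 0, 1, 1], m=2, alpha=[1.0, 0.0])
        with pytest.raises(ValueError, match="zero-probability"):
            harmony(two_clique_graph, model)


class TestYangStep:
    def test_matching_column_joins_its_cluster(self):
        # item 4 interacts exactly with cluster 0's members
        x = np.zeros((5, 5), dtype=np.int8)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            x[i, j] = x[j, i] = 1
        x[4, 0] = x[0, 4] = x[4, 1] = x[1, 4] = x[4, 2] = x[2, 4] = 1
        model = _sym_model([0, 0, 0, 1, 1], m=2, eps=0.05,
                           alpha=[0.5, 0.5])
        out = yang_step(x, model)
        assert out.item_assign[4] == 0

    def test_tie_break_goes_to_lowest_cluster_index(self):
        # two isolated items, both in cluster 1: the first sees empty
        # clusters either way (a tie) and must move to index 0
        x = np.zeros((2, 2), dtype=np.int8)
        model = _sym_model([1, 1], m=2, eps=0.05, alpha=[0.5, 0.5])
        out = yang_step(x, model)
        assert out.item_assign.tolist() == [0, 1]

    def test_isolated_nodes_prefer_small_clusters(self):
        # an even split of non-interacting items is a fixed point: each item
        # sticks with the smallest cluster available (fewest spurious pairs)
        x = np.zeros((4, 4), dtype=np.int8)
        model = _sym_model([0, 0, 1, 1], m=2, eps=0.05, alpha=[0.5, 0.5])
        out = yang_step(x, model)
        assert out.item_assign.tolist() == [0, 0, 1, 1]

    def test_reaches_truth_from_one_off_assignment(self, two_clique_graph):
        model = _sym_model([0, 0, 1, 0], m=2, eps=0.05, alpha=[0.5, 0.5])
        out = yang_step(two_clique_graph, model)
        assert out.item_assign.tolist() in ([0, 0, 1, 1], [1, 1, 0, 0])
        # and exactly one 1 per column of Y afterwards
        assert (out.Y.sum(axis=0) == 1).all()


class TestYingStep:
    def test_perfect_reconstruction_smoothed_eps(self, two_clique_graph):
        model = _sym_model([0, 0, 1, 1], m=2)
        out = ying_step(two_clique_graph, model)
        assert out.eps == pytest.approx(1 / (6 + 2))  # P = C(4,2), D = 0

    def test_equal_clusters_give_uniform_alpha(self):
        x = np.zeros((10, 10))
        model = _sym_model([0] * 5 + [1] * 5, m=2)
        out = ying_step(x, model)
        assert out.alpha.tolist() == [0.5, 0.5]  # (5+1)/(10+2)

    def test_alpha_normalized_after_pruning(self):
        x = np.zeros((8, 8))
        model = _sym_model([0] * 5 + [2] * 3, m=3)
        out = model_selection_step(ying_step(x, model))
        assert out.alpha.sum() == pytest.approx(1.0)
        assert out.m == 2


class TestModelSelection:
    def test_empty_cluster_pruned(self):
        model = _sym_model([0] * 5 + [2] * 3, m=3)
        out = model_selection_step(model)
        assert out.m == 2
        assert np.bincount(out.item_assign).tolist() == [5, 3]

    def test_identity_without_empty_clusters(self):
        model = _sym_model([0, 0, 1], m=2)
        assert model_selection_step(model) is model

    def test_likelihood_part_unchanged(self, two_clique_graph):
        x = two_clique_graph.astype(float)
        model = ying_step(x, _sym_model([0, 0, 2, 2], m=3))
        pruned = model_selection_step(model)
        # assignments survive untouched and the kappa=1 harmony can only
        # improve: renormalizing alpha upweights every occupied cluster
        assert (pruned.item_assign == np.array([0, 0, 1, 1])).all()
        assert harmony(x, pruned) >= harmony(x, model)


class TestFit:
    def test_planted_triples_recovered(self):
        cs = generate_planted_complexes(5, (3, 3), seed=1)
        g = complexes_to_graph(cs)
        truth = {frozenset(m) for m in cs.members()}
        hits = 0
        for seed in range(10):
            model, _ = fit_multi(g.adjacency, FitConfig(m_init=20, restarts=3, seed=seed * 100))
            clusters = model_to_clusters(model, g.nodes)
            hits += {frozenset(m) for m in clusters.members()} == truth
        assert hits >= 9

    def test_empty_matrix_single_cluster_is_enumeration_optimal(self):
        # for an interaction-free matrix the harmony optimum is a single
        # cluster (all "interactions" explained as noise); enumeration at
        # N=6 confirms it, and a fit started there stays there
        x = np.zeros((6, 6), dtype=np.int8)
        best = helpers.enumerate_max_harmony(x, m_max=3)
        assert helpers.brute_harmony_symmetric(x, [0] * 6) == pytest.approx(best)
        res = fit(x, FitConfig(m_init=1, seed=0))
        assert res.model.m == 1
        assert res.harmony == pytest.approx(best)

    def test_trace_monotone_and_m_nonincreasing(self):
        cs = generate_planted_complexes(8, (3, 6), seed=3)
        x = complexes_to_graph(cs).adjacency
        res = fit(x, FitConfig(m_init=30, seed=5))
        hs = [r.harmony for r in res.trace]
        ms = [r.m for r in res.trace]
        tol = 1e-9 * (x.shape[0] * (x.shape[0] - 1) / 2)
        assert all(b >= a - tol for a, b in zip(hs, hs[1:]))
        assert all(b <= a for a, b in zip(ms, ms[1:]))
        assert res.model.m <= min(30, x.shape[0])

    def test_deterministic(self, two_clique_graph):
        a = fit(two_clique_graph, FitConfig(m_init=3, seed=7))
        b = fit(two_clique_graph, FitConfig(m_init=3, seed=7))
        assert (a.model.item_assign == b.model.item_assign).all()
        assert a.harmony == b.harmony


class TestFitMulti:
    def test_single_restart_equals_fit(self, two_clique_graph):
        cfg = FitConfig(m_init=3, seed=11, restarts=1)
        single = fit(two_clique_graph, cfg)
        model, results = fit_multi(two_clique_graph, cfg)
        assert len(results) == 1
        assert (model.item_assign == single.model.item_assign).all()

    def test_best_of_restarts_dominates_first(self):
        cs = generate_planted_complexes(6, (3, 5), seed=2)
        x = complexes_to_graph(cs).adjacency
        _, results = fit_multi(x, FitConfig(m_init=15, seed=0, restarts=10))
        assert max(r.harmony for r in results) >= results[0].harmony

    def test_matches_true_partition_harmony(self):
        cs = generate_planted_complexes(5, (3, 3), seed=4)
        g = complexes_to_graph(cs)
        labels = {v: i for i, (_, members) in enumerate(cs) for v in members}
        truth = [labels[v] for v in g.nodes]
        h_true = helpers.brute_harmony_symmetric(g.adjacency, truth)
        model, results = fit_multi(g.adjacency, FitConfig(m_init=15, restarts=10, seed=0))
        assert max(r.harmony for r in results) == pytest.approx(h_true)


class TestClusterExport:
    def test_direct_mapping(self):
        model = _sym_model([0, 0, 1], m=2)
        cs = model_to_clusters(model, ["n1", "n2", "n3"])
        assert cs.members() == [frozenset({"n1", "n2"}), frozenset({"n3"})]

    def test_partition_covers_all_items(self):
        cs0 = generate_planted_complexes(6, (3, 5), seed=8)
        g = complexes_to_graph(cs0)
        model, _ = fit_multi(g.adjacency, FitConfig(m_init=15, restarts=3, seed=0))
        clusters = model_to_clusters(model, g.nodes)
        assert sum(clusters.sizes) == g.n_nodes
        assert len(clusters) == model.m
        assert clusters.partition

    def test_biclusters_from_symmetric_model_rejected(self):
        model = _sym_model([0, 0, 1], m=2)
        with pytest.raises(ValueError, match="rectangular"):
            model_to_biclusters(model)
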