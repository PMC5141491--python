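"""Minimum spanning tree construction, topology metrics, dissimilarity."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mstnet import (
    ConnectivityMatrix,
    SpanningTree,
    build_mst,
    compute_metrics,
    diameter,
    kappa,
    leaf_fraction,
    mst_dissimilarity,
    reference_tree,
    subject_mst_summary,
    tree_hierarchy,
)
from mstnet.mst import _max_betweenness

from conftest import prufer_trees, tree_weight


def star(n: int) -> SpanningTree:
    return SpanningTree(n_nodes=n, edges=frozenset((0, i) for i in range(1, n)))


def path(n: int) -> SpanningTree:
    return SpanningTree(n_nodes=n, edges=frozenset((i, i + 1) for i in range(n - 1)))


def pli_mat(w: np.ndarray) -> ConnectivityMatrix:
    labels = tuple(f"CH{i:02d}" for i in range(w.shape[0]))
    return ConnectivityMatrix(weights=w, labels=labels)


def random_pli(rng, n: int) -> ConnectivityMatrix:
    w = np.triu(rng.uniform(0, 1, (n, n)), 1)
    return pli_mat(w + w.T)


class TestBuildMst:
    def test_three_node_example(self):
        # PLI: AB 0.9, AC 0.5, BC 0.4 -> keep the two strongest links
        w = np.array([[0, 0.9, 0.5], [0.9, 0, 0.4], [0.5, 0.4, 0]])
        tree = build_mst(pli_mat(w))
        assert tree.edges == frozenset({(0, 1), (0, 2)})

    def test_all_equal_weights_still_a_tree(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 0.0)
        tree = build_mst(pli_mat(w))
        assert len(tree.edges) == 5

    def test_deterministic_under_ties(self):
        w = np.full((5, 5), 0.5)
        np.fill_diagonal(w, 0.0)
        assert build_mst(pli_mat(w)).edges == build_mst(pli_mat(w)).edges

    def test_matches_exhaustive_minimum_on_random_instances(self, rng):
        """Kruskal equals the Prufer-enumeration brute-force minimum (N=6)."""
        trees = list(prufer_trees(6))
        for _ in range(20):
            mat = random_pli(rng, 6)
            dist = 1.0 - mat.weights
            best = min(tree_weight(t, dist) for t in trees)
            got = tree_weight(build_mst(mat).edges, dist)
            assert got == pytest.approx(best, abs=1e-12)

    def test_nan_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            build_mst(pli_mat(w))


class TestMetricsClosedForms:
    @pytest.mark.parametrize("n", [4, 10, 58])
    def test_star(self, n):
        t = star(n)
        assert leaf_fraction(t) == (n - 1) / n
        assert diameter(t) == 2 / (n - 1)
        assert kappa(t) == n / 2
        assert tree_hierarchy(t) == 0.5

    @pytest.mark.parametrize("n", [4, 10, 58])
    def test_path(self, n):
        t = path(n)
        assert leaf_fraction(t) == 2 / n
        assert diameter(t) == 1.0
        assert kappa(t) == pytest.approx((2 * n - 3) / (n - 1), rel=1e-14)

    def test_path_kappa_limit_approaches_two(self):
        assert 1.99 < kappa(path(1000)) < 2.0

    def test_two_node_tree_all_leaves(self):
        assert leaf_fraction(path(2)) == 1.0

    def test_path_hierarchy_n5(self):
        # middle node carries 4 of the 6 pairs: Th = 2 / (2*4*(2/3))
        assert tree_hierarchy(path(5)) == pytest.approx(0.375, abs=1e-14)

    def test_hierarchy_undefined_below_three_nodes(self):
        with pytest.raises(ValueError, match="3 nodes"):
            tree_hierarchy(path(2))

    def test_diameter_unnormalized_switch(self):
        assert diameter(path(8), normalize=False) == 7.0


class TestMetricProperties:
    def test_diameter_matches_bfs_oracle_on_random_trees(self, rng):
        for edges in itertools.islice(prufer_trees(8), 0, 4096, 97):
            t = SpanningTree(n_nodes=8, edges=edges)
            g = nx.Graph(list(edges))
            oracle = max(
                nx.eccentricity(g, v) for v in g.nodes
            )
            assert diameter(t, normalize=False) == oracle

    def test_max_betweenness_matches_networkx(self, rng):
        for edges in itertools.islice(prufer_trees(7), 0, 16807, 611):
            t = SpanningTree(n_nodes=7, edges=edges)
            g = nx.Graph(list(edges))
            expected = max(nx.betweenness_centrality(g, normalized=True).values())
            assert _max_betweenness(t) == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        edges = frozenset({(0, 1), (1, 2), (1, 3), (3, 4), (3, 5)})
        t = SpanningTree(n_nodes=6, edges=edges)
        perm = rng.permutation(6)
        permuted = frozenset(
            (min(perm[u], perm[v]), max(perm[u], perm[v])) for u, v in edges
        )
        tp = SpanningTree(n_nodes=6, edges=permuted)
        for fn in (leaf_fraction, diameter, kappa, tree_hierarchy):
            assert fn(t) == pytest.approx(fn(tp), abs=1e-12)

    def test_leaf_fraction_bounded_by_path_and_star(self):
        for edges in itertools.islice(prufer_trees(7), 0, 16807, 131):
            t = SpanningTree(n_nodes=7, edges=edges)
            assert 2 / 7 <= leaf_fraction(t) <= 6 / 7


class TestDissimilarity:
    def test_self_dissimilarity_zero(self):
        assert mst_dissimilarity(star(6), star(6)) == 0.0

    def test_star_vs_path_four_nodes(self):
        # only edge (0,1) is shared: D = 1 - 1/3
        assert mst_dissimilarity(star(4), path(4)) == pytest.approx(2 / 3)

    def test_edge_disjoint_trees(self):
        a = path(4)
        b = SpanningTree(n_nodes=4, edges=frozenset({(0, 2), (0, 3), (1, 3)}))
        assert not (a.edges & b.edges)
        assert mst_dissimilarity(a, b) == 1.0

    def test_symmetry_and_triangle_inequality(self, rng):
        pool = [e for i, e in enumerate(prufer_trees(6)) if i % 113 == 0]
        trees = [SpanningTree(n_nodes=6, edges=e) for e in pool]
        for a, b, c in itertools.islice(itertools.combinations(trees, 3), 30):
            dab = mst_dissimilarity(a, b)
            assert dab == mst_dissimilarity(b, a)
            assert dab <= mst_dissimilarity(a, c) + mst_dissimilarity(c, b) + 1e-12

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node sets"):
            mst_dissimilarity(star(4), star(5))


class TestReferenceTree:
    def test_single_control_is_its_own_mst(self, rng):
        mat = random_pli(rng, 6)
        assert reference_tree([mat]).edges == build_mst(mat).edges

    def test_repeated_matrices_equal_single_copy(self, rng):
        mat = random_pli(rng, 6)
        assert reference_tree([mat] * 5).edges == reference_tree([mat]).edges

    def test_mean_matrix_mst_verified_by_enumeration(self, rng):
        mats = [random_pli(rng, 6) for _ in range(2)]
        ref = reference_tree(mats)
        mean_dist = 1.0 - np.mean([m.weights for m in mats], axis=0)
        best = min(tree_weight(t, mean_dist) for t in prufer_trees(6))
        assert tree_weight(ref.edges, mean_dist) == pytest.approx(best, abs=1e-12)


class TestSubjectSummary:
    def test_identical_epochs_equal_single_epoch(self, rng):
        mat = random_pli(rng, 6)
        per_epoch, subject = subject_mst_summary([mat] * 4)
        assert subject == per_epoch[0]

    def test_metric_level_averaging(self):
        # epoch MSTs: a star (leaf fraction 5/6) and a path (2/6) -> mean
        w_star = np.zeros((6, 6))
        for i in range(1, 6):
            w_star[0, i] = w_star[i, 0] = 0.9
        w_path = np.zeros((6, 6))
        for i in range(5):
            w_path[i, i + 1] = w_path[i + 1, i] = 0.9
        mats = [pli_mat(w_star), pli_mat(w_path)]
        _, subject = subject_mst_summary(mats)
        assert subject.leaf_fraction == pytest.approx((5 / 6 + 2 / 6) / 2)

    def test_mean_matrix_mode(self, rng):
        mats = [random_pli(rng, 6) for _ in range(3)]
        _, subject = subject_mst_summary(mats, aggregation="mean_matrix")
        mean_mat = pli_mat(np.mean([m.weights for m in mats], axis=0))
        expected = compute_metrics(build_mst(mean_mat))
        assert subject.leaf_fraction == expected.leaf_fraction
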