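"""Weighted graph measures against hand values and brute-force enumeration."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from hubcog.metrics import (
    assortativity,
    betweenness,
    clustering,
    compute_metrics,
    edge_lengths,
    local_efficiency,
    nodal_strength,
    path_length_stats,
    _shortest_path_matrix,
)

from oracles import (
    brute_betweenness,
    brute_clustering_zhang,
    brute_distance_matrix,
    brute_global_efficiency,
    brute_local_efficiency_wang,
    random_connected_weights,
)


class TestHandValues:
    def test_edge_lengths_reciprocal(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        L = edge_lengths(w)
        assert L[0, 1] == 2.0 and np.isinf(L[0, 0])
        w[0, 1] = w[1, 0] = 0.0
        assert np.isinf(edge_lengths(w)[0, 1])

    def test_strength_triangle(self, triangle):
        nm, _ = compute_metrics(triangle)
        assert np.allclose(nm.values["strength"], [0.7, 0.5, 0.8])

    def test_strength_sums_to_twice_upper_triangle(self, rng):
        w = random_connected_weights(rng, 7)
        assert nodal_strength(w).sum() == pytest.approx(
            2 * np.triu(w, 1).sum(), rel=1e-12)

    def test_path_chain_reciprocals(self, make):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        nm, gm = compute_metrics(make(w))
        d = _shortest_path_matrix(w)
        assert d[0, 2] == 4.0
        assert np.allclose(nm.values["path_length"], [3.0, 2.0, 3.0])
        assert gm.values["char_path_length"] == pytest.approx(8 / 3)

    def test_complete_unit_graph(self, make):
        w = 1.0 - np.eye(5)
        nm, gm = compute_metrics(make(w))
        assert gm.values["char_path_length"] == 1.0
        assert gm.values["global_efficiency"] == 1.0
        assert np.allclose(nm.values["betweenness"], 0.0)
        assert np.allclose(nm.values["clustering"], 1.0)
        assert np.allclose(nm.values["local_efficiency"], 1.0)

    def test_two_node_efficiency_equals_weight(self, make):
        w = np.array([[0.0, 0.25], [0.25, 0.0]])
        _, gm = compute_metrics(make(w), metrics=("path_length",))
        assert gm.values["global_efficiency"] == pytest.approx(0.25)

    def test_path_graph_betweenness(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert np.allclose(betweenness(w), [0.0, 1.0, 0.0])

    def test_star_center_local_efficiency_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        for variant in ("wang", "latora"):
            assert local_efficiency(w, variant)[0] == 0.0

    def test_star_assortativity_negative(self):
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = 1.0
        r, _ = assortativity(w)
        assert r < 0

    def test_regular_ring_assortativity_undefined(self):
        w = np.zeros((6, 6))
        for i in range(6):
            w[i, (i + 1) % 6] = w[(i + 1) % 6, i] = 1.0
        r, local = assortativity(w)
        assert np.isnan(r) and np.isnan(local).all()


class TestBruteForceOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_distances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = random_connected_weights(rng, rng.integers(4, 8))
        assert np.allclose(_shortest_path_matrix(w), brute_distance_matrix(w),
                           rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_betweenness_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        w = random_connected_weights(rng, rng.integers(4, 8))
        assert np.allclose(betweenness(w), brute_betweenness(w), atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_efficiency_and_clustering_match_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        w = random_connected_weights(rng, 6)
        _, char_L, e_glob, _ = path_length_stats(_shortest_path_matrix(w))
        assert e_glob == pytest.approx(brute_global_efficiency(w), rel=1e-9)
        assert np.allclose(clustering(w, "wang"), brute_clustering_zhang(w),
                           rtol=1e-9)
        assert np.allclose(local_efficiency(w, "wang"),
                           brute_local_efficiency_wang(w), rtol=1e-9)

    def test_length_monotone_in_weight(self, rng):
        w = random_connected_weights(rng, 6, p=1.0)
        L = edge_lengths(w)
        iu = np.triu_indices(6, 1)
        order_w = np.argsort(w[iu])
        order_L = np.argsort(-L[iu])
        assert np.array_equal(order_w, order_L)


class TestBinaryReduction:
    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_formulas_reduce_to_binary(self, seed):
        """On 0/1 matrices every weighted generalization must equal the
        textbook binary value (networkx as reference)."""
        rng = np.random.default_rng(300 + seed)
        a = (random_connected_weights(rng, 8, p=0.5) > 0).astype(float)
        g = nx.from_numpy_array(a)
        deg = a.sum(1)
        nx_clust = np.array([nx.clustering(g, i) for i in range(8)])
        for variant in ("wang", "onnela"):
            assert np.allclose(clustering(a, variant), nx_clust, atol=1e-12)
        nx_leff = np.array([
            nx.global_efficiency(g.subgraph(list(g.neighbors(i))))
            if deg[i] >= 2 else 0.0
            for i in range(8)
        ])
        for variant in ("wang", "latora"):
            assert np.allclose(local_efficiency(a, variant), nx_leff, atol=1e-12)
        assert np.array_equal(nodal_strength(a), deg)
        d = _shortest_path_matrix(a)
        spl = dict(nx.all_pairs_shortest_path_length(g))
        for i in range(8):
            for j in range(8):
                if i != j and j in spl[i]:
                    assert d[i, j] == spl[i][j]


class TestStructuralProperties:
    def test_relabeling_equivariance(self, rng, make):
        w = random_connected_weights(rng, 9)
        perm = rng.permutation(9)
        nm1, gm1 = compute_metrics(make(w))
        nm2, gm2 = compute_metrics(make(w[np.ix_(perm, perm)]))
        for m, v in nm1.values.items():
            assert np.allclose(v[perm], nm2.values[m], rtol=1e-9, atol=1e-12), m
        for m, v in gm1.values.items():
            assert v == pytest.approx(gm2.values[m], rel=1e-9)

    def test_assortativity_decomposition_sums_to_global(self, rng):
        for _ in range(10):
            w = random_connected_weights(rng, 10, p=0.5)
            r, local = assortativity(w)
            if np.isfinite(r):
                assert np.nansum(local) == pytest.approx(r, abs=1e-9)

    def test_compute_all_consistent_with_individual_ops(self, rng, make):
        for _ in range(5):
            w = random_connected_weights(rng, 8)
            nm, gm = compute_metrics(make(w))
            assert np.allclose(nm.values["strength"], nodal_strength(w))
            assert np.allclose(nm.values["betweenness"], betweenness(w))
            assert np.allclose(nm.values["clustering"], clustering(w, "wang"))
            r, local = assortativity(w)
            assert gm.values["assortativity"] == pytest.approx(r, nan_ok=True)

    def test_removed_nodes_get_nan_and_are_excluded(self, rng, make):
        w = random_connected_weights(rng, 7, p=1.0)
        w[3, :] = w[:, 3] = 0.0
        c = make(w, removed={3: "floating"})
        nm, gm = compute_metrics(c)
        for v in nm.values.values():
            assert np.isnan(v[3]) and np.isfinite(np.delete(v, 3)).all()
        sub = np.delete(np.delete(w, 3, 0), 3, 1)
        nm2, gm2 = compute_metrics(make(sub))
        assert np.allclose(np.delete(nm.values["path_length"], 3),
                           nm2.values["path_length"])

    def test_disconnected_retained_node_is_an_error(self, make):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        with pytest.raises(ValueError, match="lh.n3"):
            compute_metrics(make(w))

    def test_efficiency_and_path_length_inversely_rank_ordered(self, rng, make):
        """Across a family of graphs, global efficiency and characteristic
        path length move in opposite directions."""
        eglob, lam = [], []
        for _ in range(15):
            w = random_connected_weights(rng, 10, p=rng.uniform(0.3, 0.9))
            _, gm = compute_metrics(make(w), metrics=("path_length",))
            eglob.append(gm.values["global_efficiency"])
            lam.append(gm.values["char_path_length"])
        rho = sps.spearmanr(eglob, lam).statistic
        assert rho < 0
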