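"""Graph metrics against brute-force and networkx oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from placebonet import (
    characteristic_pathlength,
    clustering_coefficient,
    random_ensemble,
    small_world,
)
from placebonet.metrics import random_graph_gnm


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


def oracle_clustering(adj):
    """Triangle enumeration over all node triples."""
    n = adj.shape[0]
    t = np.zeros(n)
    for i, j, k in itertools.combinations(range(n), 3):
        if adj[i, j] and adj[j, k] and adj[i, k]:
            t[[i, j, k]] += 1
    k_deg = adj.sum(1)
    ci = np.zeros(n)
    for i in range(n):
        if k_deg[i] >= 2:
            ci[i] = 2 * t[i] / (k_deg[i] * (k_deg[i] - 1))
    return ci.mean(), ci


def oracle_distances(adj):
    """Floyd-Warshall on a small graph."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def oracle_pathlength_printed(adj):
    n = adj.shape[0]
    d = oracle_distances(adj)
    inv = np.where(np.isfinite(d) & (d > 0), 1 / np.where(d > 0, d, 1), 0.0)
    np.fill_diagonal(inv, 0.0)
    return (inv.sum(1) / (n - 1)).mean()


class TestClustering:
    def test_complete_graph_is_one(self):
        k4 = adj_from_edges(4, itertools.combinations(range(4), 2))
        assert clustering_coefficient(k4)[0] == 1.0

    def test_star_has_no_triangles(self):
        star = adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coefficient(star)[0] == 0.0

    def test_five_node_example_matches_enumeration(self):
        adj = adj_from_edges(5, [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4)])
        c, ci = clustering_coefficient(adj)
        oc, oci = oracle_clustering(adj)
        assert c == pytest.approx(oc, abs=1e-12)
        np.testing.assert_allclose(ci, oci, atol=1e-12)

    def test_matches_networkx_on_random_graphs(self):
        for seed in range(5):
            adj = random_graph_gnm(30, 120, np.random.default_rng(seed))
            c, ci = clustering_coefficient(adj)
            nxc = nx.clustering(nx.from_numpy_array(adj))
            np.testing.assert_allclose(ci, [nxc[i] for i in range(30)], atol=1e-12)

    def test_nodal_triangle_identity(self):
        # nodal form aggregates to 3 * triangles / connected triples
        rng = np.random.default_rng(7)
        adj = random_graph_gnm(20, 60, rng)
        _, ci = clustering_coefficient(adj)
        k = adj.sum(1)
        triples = (k * (k - 1) / 2).sum()
        tri = np.trace(np.linalg.matrix_power(adj.astype(float), 3)) / 6
        assert (ci * k * (k - 1) / 2).sum() == pytest.approx(3 * tri, abs=1e-9)
        assert triples >= 3 * tri


class TestPathlength:
    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_complete_graph_printed_form_is_one(self, n):
        kn = adj_from_edges(n, itertools.combinations(range(n), 2))
        assert characteristic_pathlength(kn)[0] == pytest.approx(1.0)
        assert characteristic_pathlength(kn, "classic")[0] == pytest.approx(1.0)

    def test_two_disjoint_edges(self):
        adj = adj_from_edges(4, [(0, 1), (2, 3)])
        assert characteristic_pathlength(adj)[0] == pytest.approx(1 / 3)

    def test_path_graph_classic(self):
        p3 = adj_from_edges(3, [(0, 1), (1, 2)])
        assert characteristic_pathlength(p3, "classic")[0] == pytest.approx(4 / 3)

    def test_printed_form_monotone_under_edge_addition(self):
        rng = np.random.default_rng(1)
        adj = random_graph_gnm(20, 30, rng)
        base = characteristic_pathlength(adj)[0]
        ii, jj = np.where(~adj & ~np.eye(20, dtype=bool))
        pick = rng.integers(len(ii))
        adj2 = adj.copy()
        adj2[ii[pick], jj[pick]] = adj2[jj[pick], ii[pick]] = True
        assert characteristic_pathlength(adj2)[0] >= base - 1e-12

    def test_empty_graph_flagged_missing(self):
        adj = np.zeros((5, 5), dtype=bool)
        assert characteristic_pathlength(adj)[0] == 0.0  # no reachable pairs
        assert np.isnan(characteristic_pathlength(adj, "classic")[0])

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            characteristic_pathlength(np.zeros((3, 3), bool), "weird")


class TestEnsembles:
    def test_gnm_members_have_exact_edge_count(self):
        adj = random_graph_gnm(30, 100, np.random.default_rng(0))
        for mem in random_ensemble(adj, n_rand=5, seed=1):
            assert mem.sum() // 2 == 100
            assert not mem.diagonal().any()
            assert np.array_equal(mem, mem.T)

    def test_rewire_preserves_degree_sequence(self):
        adj = random_graph_gnm(30, 100, np.random.default_rng(2))
        for mem in random_ensemble(adj, n_rand=3, model="rewire", seed=1):
            np.testing.assert_array_equal(mem.sum(1), adj.sum(1))
            assert mem.sum() // 2 == 100

    def test_gnm_clustering_matches_er_expectation(self):
        # E[C] ~ p = 2m / (n(n-1)) for G(n, m)
        adj = random_graph_gnm(78, 1291, np.random.default_rng(3))
        cs = [clustering_coefficient(a)[0]
              for a in random_ensemble(adj, n_rand=50, seed=5)]
        cs = np.array(cs)
        se = cs.std(ddof=1) / np.sqrt(len(cs))
        assert cs.mean() == pytest.approx(1291 / 3003, abs=3 * se + 1e-3)

    def test_ensemble_reproducible_under_seed(self):
        adj = random_graph_gnm(20, 50, np.random.default_rng(4))
        a = random_ensemble(adj, n_rand=3, seed=9)
        b = random_ensemble(adj, n_rand=3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_oversized_m_rejected(self):
        with pytest.raises(ValueError):
            random_graph_gnm(5, 11, np.random.default_rng(0))


class TestSmallWorld:
    def test_complete_graph_normalizers_are_unity(self):
        kn = adj_from_edges(6, itertools.combinations(range(6), 2))
        ms = small_world(kn, n_rand=5, seed=0)
        assert ms.clustering_norm == pytest.approx(1.0)
        assert ms.pathlength_norm == pytest.approx(1.0)
        assert ms.smallworld == pytest.approx(1.0)

    def test_rewired_ring_lattice_is_small_world(self):
        G = nx.watts_strogatz_graph(78, 16, 0.05, seed=1)
        adj = nx.to_numpy_array(G, dtype=bool)
        ms = small_world(adj, n_rand=10, seed=2)
        assert ms.smallworld > 1.0
        assert ms.clustering_norm > 1.0

    def test_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(5)
        adj = random_graph_gnm(40, 200, rng)
        perm = rng.permutation(40)
        adj_p = adj[np.ix_(perm, perm)]
        assert clustering_coefficient(adj)[0] == pytest.approx(
            clustering_coefficient(adj_p)[0], abs=1e-12
        )
        assert characteristic_pathlength(adj)[0] == pytest.approx(
            characteristic_pathlength(adj_p)[0], abs=1e-12
        )

    def test_metric_set_carries_ensemble_provenance(self):
        adj = random_graph_gnm(20, 60, np.random.default_rng(6))
        ms = small_world(adj, n_rand=4, seed=11, model="gnm")
        assert ms.n_rand == 4 and ms.ensemble_seed == 11
        assert ms.n_edges == 60 and ms.n_nodes == 20
        assert 0 <= ms.clustering <= 1

    def test_validation_rejects_directed_or_looped_input(self):
        bad = np.zeros((4, 4), bool)
        bad[0, 1] = True  # asymmetric
        with pytest.raises(ValueError):
            clustering_coefficient(bad)
        loop = np.eye(4, dtype=bool)
        with pytest.raises(ValueError):
            clustering_coefficient(loop)


class TestExhaustiveSmall:
    """Formula implementations equal brute-force oracles on all tiny graphs."""

    def test_all_graphs_up_to_five_nodes(self):
        for n in (2, 3, 4, 5):
            pairs = list(itertools.combinations(range(n), 2))
            for mask in range(1 << len(pairs)):
                edges = [p for b, p in enumerate(pairs) if mask >> b & 1]
                adj = adj_from_edges(n, edges)
                c, _ = clustering_coefficient(adj)
                assert c == pytest.approx(oracle_clustering(adj)[0], abs=1e-12)
                l_printed, _ = characteristic_pathlength(adj)
                assert l_printed == pytest.approx(
                    oracle_pathlength_printed(adj), abs=1e-12
                )
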