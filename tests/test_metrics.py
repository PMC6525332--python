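"""Graph measures against closed forms, brute-force oracles and networkx."""

import numpy as np
import pytest

import networkx as nx

from zfnet import oracles
from zfnet.experiments import random_graphs
from zfnet.metrics import (
    assortativity,
    characteristic_path_length,
    clustering,
    degrees,
    graph_summary,
    transitivity,
    triangle_counts,
)
from .conftest import bnet_from_edges


class TestClosedForms:
    def test_triangle_fully_clustered(self):
        k3 = bnet_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        c, cl = clustering(k3)
        assert np.allclose(c, 1.0) and cl == 1.0
        assert transitivity(k3) == 1.0

    def test_path_has_no_triangles(self):
        p3 = bnet_from_edges(3, [(0, 1), (1, 2)])
        c, cl = clustering(p3)
        assert np.allclose(c, 0.0) and cl == 0.0

    def test_k4_minus_edge_clustering(self, k4_minus_edge):
        # degree-3 nodes close 2 of 3 neighbor pairs; degree-2 nodes 1 of 1
        c, cl = clustering(k4_minus_edge)
        assert np.allclose(sorted(c), [2 / 3, 2 / 3, 1.0, 1.0])
        assert cl == pytest.approx(5 / 6, abs=1e-15)

    def test_k4_minus_edge_transitivity_differs_from_cl(self, k4_minus_edge):
        # Σ2t = 12, Σk(k−1) = 16 — transitivity down-weights the low-degree nodes
        assert transitivity(k4_minus_edge) == pytest.approx(0.75, abs=1e-15)

    def test_complete_graph_path_length_one(self, complete4):
        l, unreachable = characteristic_path_length(complete4)
        assert l == 1.0 and unreachable == 0

    def test_cycle5_path_length(self, cycle5):
        l, _ = characteristic_path_length(cycle5)
        assert l == pytest.approx(1.5, abs=1e-15)

    def test_star_is_triangle_free_and_disassortative(self, star4):
        assert transitivity(star4) == 0.0
        assert assortativity(star4) == pytest.approx(-1.0, abs=1e-12)

    def test_complete_graph_assortativity_undefined(self, complete4):
        assert np.isnan(assortativity(complete4))

    def test_degrees(self, star4, complete4):
        assert degrees(star4).tolist() == [3, 1, 1, 1]
        assert degrees(complete4).tolist() == [3, 3, 3, 3]
        empty = bnet_from_edges(3, [])
        assert degrees(empty).tolist() == [0, 0, 0]

    def test_degree_sum_is_twice_edges(self, k4_minus_edge):
        assert degrees(k4_minus_edge).sum() == 2 * k4_minus_edge.n_edges

    def test_empty_graph_path_length_undefined(self):
        l, unreachable = characteristic_path_length(bnet_from_edges(3, []))
        assert np.isnan(l) and unreachable == 6

    def test_assortativity_requires_edges(self):
        with pytest.raises(ValueError):
            assortativity(bnet_from_edges(3, []))


@pytest.fixture(scope="module")
def graphs():
    return random_graphs(200, seed=7, n_max=12)


class TestOracleEquivalence:
    """200 seeded random graphs with n ≤ 12 against brute force and networkx."""

    def test_matches_brute_force(self, graphs):
        for bnet in graphs:
            a = bnet.adjacency
            c, cl = clustering(bnet)
            c_ref, cl_ref = oracles.brute_clustering(a)
            assert np.abs(c - c_ref).max() < 1e-12
            assert abs(cl - cl_ref) < 1e-12
            l, u = characteristic_path_length(bnet)
            l_ref, u_ref = oracles.brute_path_length(a)
            assert u == u_ref
            assert (np.isnan(l) and np.isnan(l_ref)) or abs(l - l_ref) < 1e-12
            t, t_ref = transitivity(bnet), oracles.brute_transitivity(a)
            assert (np.isnan(t) and np.isnan(t_ref)) or abs(t - t_ref) < 1e-12
            if bnet.n_edges > 0:
                r, r_ref = assortativity(bnet), oracles.brute_assortativity(a)
                assert (np.isnan(r) and np.isnan(r_ref)) or abs(r - r_ref) < 1e-12

    def test_matches_networkx(self, graphs):
        for bnet in graphs[:60]:
            g = nx.from_numpy_array(bnet.adjacency)
            _, cl = clustering(bnet)
            assert cl == pytest.approx(nx.average_clustering(g), abs=1e-12)
            tri = triangle_counts(bnet)
            assert tri.tolist() == [nx.triangles(g, i) for i in range(bnet.n)]
            t = transitivity(bnet)
            t_nx = nx.transitivity(g)
            if np.isnan(t):
                assert t_nx == 0  # networkx coerces the 0/0 case to 0
            else:
                assert t == pytest.approx(t_nx, abs=1e-12)
            if bnet.n_edges > 0:
                r = assortativity(bnet)
                with np.errstate(invalid="ignore", divide="ignore"):
                    r_nx = nx.degree_assortativity_coefficient(g)
                if not (np.isnan(r) or np.isnan(r_nx)):
                    assert r == pytest.approx(r_nx, abs=1e-9)


class TestInvariants:
    def test_isomorphism_invariance(self, rng):
        for bnet in random_graphs(20, seed=3, n_max=10):
            perm = rng.permutation(bnet.n)
            shuffled = bnet_from_edges(
                bnet.n,
                [(perm[i], perm[j]) for i, j in zip(*np.triu_indices(bnet.n, 1))
                 if bnet.adjacency[i, j]],
            )
            assert clustering(bnet)[1] == pytest.approx(
                clustering(shuffled)[1], abs=1e-12)
            l1, u1 = characteristic_path_length(bnet)
            l2, u2 = characteristic_path_length(shuffled)
            assert u1 == u2
            assert (np.isnan(l1) and np.isnan(l2)) or l1 == pytest.approx(l2, abs=1e-12)

    def test_regular_graph_cl_equals_transitivity(self, cycle5, complete4):
        for g in (cycle5, complete4):
            assert clustering(g)[1] == pytest.approx(transitivity(g), abs=1e-14)

    def test_adding_edge_never_increases_l_on_connected_graphs(self, rng):
        for bnet in random_graphs(30, seed=11, n_max=9):
            l0, u0 = characteristic_path_length(bnet)
            if u0 > 0:  # restrict to a fixed reachable-pair set
                continue
            absent = [(i, j) for i, j in zip(*np.triu_indices(bnet.n, 1))
                      if not bnet.adjacency[i, j]]
            if not absent:
                continue
            i, j = absent[rng.integers(len(absent))]
            denser = bnet_from_edges(
                bnet.n,
                [(a, b) for a, b in zip(*np.triu_indices(bnet.n, 1))
                 if bnet.adjacency[a, b]] + [(i, j)],
            )
            l1, _ = characteristic_path_length(denser)
            assert l1 <= l0 + 1e-12

    def test_triangle_bound(self):
        for bnet in random_graphs(50, seed=5, n_max=12):
            k = degrees(bnet)
            t = triangle_counts(bnet)
            assert np.all(t <= k * (k - 1) // 2)

    def test_graph_summary_consistency(self, k4_minus_edge):
        s = graph_summary(k4_minus_edge)
        assert s.n == 4 and s.n_edges == 5
        assert s.cl == pytest.approx(5 / 6)
        assert s.t == pytest.approx(0.75)
        assert s.density == pytest.approx(5 / 6)
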