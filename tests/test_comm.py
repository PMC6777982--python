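"""Routing, efficiency and lesion geometry on weighted spatial networks."""

import itertools

import numpy as np
import pytest

from lagnav.comm import (
    DEFAULT_DENSITIES,
    CommunicationModel,
    auc_over_densities,
    efficiency,
    euclidean_matrix,
    navigate,
    region_to_lesion_distance,
    shortest_paths,
    threshold_density,
    weight_to_length,
)
from lagnav.datatypes import Connectome, SubjectRecord
from tests.conftest import random_length_graph


def make_conn(W, coords=None):
    n = W.shape[0]
    if coords is None:
        coords = np.random.default_rng(0).uniform(-50, 50, (n, 3))
    return Connectome(W, coords, np.arange(n))


def brute_force_sp(L):
    """Exhaustive path enumeration over all simple paths (oracle)."""
    n = L.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    nodes = range(n)
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            for r in range(n - 1):
                for mid in itertools.permutations(set(nodes) - {i, j}, r):
                    path = (i, *mid, j)
                    cost = sum(L[a, b] for a, b in zip(path, path[1:]))
                    best[i, j] = min(best[i, j], cost)
    return best


def greedy_walk_oracle(L, coords, i, j):
    """Independent step-by-step simulation of greedy spatial routing."""
    n = L.shape[0]
    dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    u, visited = i, {i}
    lsum = dsum = hops = 0.0
    while True:
        nbrs = [v for v in range(n) if v != u and np.isfinite(L[u, v])]
        if not nbrs:
            return np.inf, np.inf, np.inf
        v = min(nbrs, key=lambda w: (dist[w, j], w))
        lsum += L[u, v]
        dsum += dist[u, v]
        hops += 1
        if v == j:
            return lsum, dsum, hops
        if v in visited:
            return np.inf, np.inf, np.inf
        visited.add(v)
        u = v


class TestThresholdDensity:
    def _complete(self, n, seed=0):
        rng = np.random.default_rng(seed)
        W = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        W[iu, ju] = rng.integers(1, 100, iu.size)
        W += W.T
        return make_conn(W)

    def test_full_density_noop(self):
        conn = self._complete(6)
        out = threshold_density(conn, 1.0)
        np.testing.assert_array_equal(out.weights, conn.weights)

    def test_half_density_edge_count(self):
        out = threshold_density(self._complete(5), 0.5)
        assert (np.count_nonzero(out.weights) // 2) == 5  # ceil(0.5 * 10)

    def test_keeps_strongest(self):
        conn = self._complete(6, seed=3)
        out = threshold_density(conn, 0.25)
        kept = out.weights[np.triu_indices(6, 1)]
        dropped_max = conn.weights[(conn.weights > 0) & (out.weights == 0)].max()
        assert kept[kept > 0].min() >= dropped_max

    def test_nesting(self):
        conn = self._complete(8, seed=5)
        e2 = threshold_density(conn, 0.2).weights > 0
        e4 = threshold_density(conn, 0.4).weights > 0
        assert np.all(e4[e2])

    def test_invalid_density(self):
        conn = self._complete(4)
        for d in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_density(conn, d)

    def test_deterministic_tie_break(self):
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            W[i, j] = W[j, i] = 7.0  # all tied
        conn = make_conn(W)
        out = threshold_density(conn, 2 / 6)  # keep 2 of 4 present edges
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(out.weights)))}
        assert kept == {(0, 1), (0, 2)}  # lexicographically first


class TestWeightToLength:
    def test_closed_form(self):
        W = np.array([[0.0, 9.0], [9.0, 0.0]])
        L = weight_to_length(make_conn(W))
        assert L[0, 1] == pytest.approx(-np.log10(9 / 10))

    def test_absent_edge_infinite_diag_zero(self):
        W = np.array([[0, 4, 0], [4, 0, 2], [0, 2, 0]], dtype=float)
        L = weight_to_length(make_conn(W))
        assert np.isinf(L[0, 2]) and np.all(np.diag(L) == 0)
        assert L[0, 1] > 0 and L[0, 1] < L[1, 2]  # monotone decreasing in w

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            weight_to_length(make_conn(np.zeros((3, 3))))

    def test_printed_form_negative_lengths(self):
        W = np.array([[0.0, 9.0], [9.0, 0.0]])
        L = weight_to_length(make_conn(W), printed_form=True)
        assert L[0, 1] < 0  # why the corrected form is the default


class TestShortestPaths:
    def test_single_edge(self):
        L = np.array([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_allclose(shortest_paths(L), L)

    def test_triangle_detour(self):
        L = np.array([[0, 5, 1], [5, 0, 1], [1, 1, 0]], dtype=float)
        sp = shortest_paths(L)
        assert sp[0, 1] == pytest.approx(2.0)  # via node 2

    def test_disconnected_inf(self):
        L = np.full((3, 3), np.inf)
        np.fill_diagonal(L, 0)
        L[0, 1] = L[1, 0] = 1.0
        sp = shortest_paths(L)
        assert np.isinf(sp[0, 2]) and sp[0, 1] == 1.0

    def test_oracle_equivalence(self):
        """Dijkstra agrees with exhaustive path enumeration on 50 graphs."""
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            L = random_length_graph(rng, n)
            np.testing.assert_allclose(shortest_paths(L), brute_force_sp(L), atol=1e-9)


class TestNavigate:
    def test_complete_graph_one_hop(self):
        rng = np.random.default_rng(2)
        n = 5
        coords = rng.uniform(-40, 40, (n, 3))
        L = rng.uniform(0.5, 2.0, (n, n))
        L = (L + L.T) / 2
        np.fill_diagonal(L, 0)
        lam, dnav, hops, _ = navigate(L, coords)
        d = euclidean_matrix(coords)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(lam[off], L[off])
        np.testing.assert_allclose(dnav[off], d[off])
        assert np.all(hops[off] == 1)

    def test_dead_end_fails(self):
        # s(0) - a(1) chain, target t(2) isolated from s's side
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [10.0, 0, 0], [11.0, 0, 0]])
        L = np.full((4, 4), np.inf)
        np.fill_diagonal(L, 0)
        L[0, 1] = L[1, 0] = 1.0
        L[2, 3] = L[3, 2] = 1.0
        lam, dnav, hops, _ = navigate(L, coords)
        assert np.isinf(lam[0, 2]) and np.isinf(dnav[0, 2]) and np.isinf(hops[0, 2])

    def test_isolated_node_fails_everywhere(self):
        coords = np.array([[0, 0, 0], [5.0, 0, 0], [9.0, 0, 0]])
        L = np.full((3, 3), np.inf)
        np.fill_diagonal(L, 0)
        L[1, 2] = L[2, 1] = 1.0
        lam, _, _, _ = navigate(L, coords)
        assert np.all(np.isinf(lam[0, 1:]))

    def test_oracle_equivalence_random_geometric(self):
        """Greedy routing matches an independent walk simulation, 50 graphs."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            coords = rng.uniform(-30, 30, (n, 3))
            L = random_length_graph(rng, n, p_edge=0.5)
            lam, dnav, hops, _ = navigate(L, coords)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    lo, do, ho = greedy_walk_oracle(L, coords, i, j)
                    assert lam[i, j] == pytest.approx(lo)
                    assert dnav[i, j] == pytest.approx(do)
                    assert hops[i, j] == pytest.approx(ho)

    def test_sp_never_longer_than_nav(self, conn10):
        L = weight_to_length(conn10)
        sp = shortest_paths(L)
        lam, dnav, _, _ = navigate(L, conn10.coords)
        assert np.all(sp <= lam + 1e-9)
        # navigation distance dominates straight-line distance on success
        d = euclidean_matrix(conn10.coords)
        ok = np.isfinite(lam)
        assert np.all(dnav[ok] >= d[ok] - 1e-9)


class TestEfficiency:
    def test_unit_graph(self):
        lam = np.ones((4, 4)) - np.eye(4)
        assert efficiency(lam) == pytest.approx(1.0)

    def test_partial_connectivity(self):
        lam = np.full((3, 3), np.inf)
        np.fill_diagonal(lam, 0)
        lam[0, 1] = lam[1, 0] = lam[0, 2] = lam[2, 0] = 1.0
        assert efficiency(lam) == pytest.approx(4 / 6)

    def test_homogeneity(self):
        rng = np.random.default_rng(8)
        lam = rng.uniform(0.5, 3.0, (5, 5))
        np.fill_diagonal(lam, 0)
        assert efficiency(3.0 * lam) == pytest.approx(efficiency(lam) / 3.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        lam = rng.uniform(0.5, 3.0, (6, 6))
        lam = (lam + lam.T) / 2
        np.fill_diagonal(lam, 0)
        perm = rng.permutation(6)
        assert efficiency(lam[np.ix_(perm, perm)]) == pytest.approx(efficiency(lam))

    def test_too_small(self):
        with pytest.raises(ValueError):
            efficiency(np.zeros((1, 1)))


class TestAucOverDensities:
    def test_grid_width(self):
        dens = np.asarray(DEFAULT_DENSITIES)
        assert dens[0] == 0.10 and dens[-1] == 0.50 and len(dens) == 9
        # constant measure c integrates to 0.40 * c
        assert np.trapezoid(np.full(9, 2.5), dens) == pytest.approx(0.40 * 2.5)

    def test_linear_measure_exact(self):
        dens = np.asarray(DEFAULT_DENSITIES)
        vals = 2.0 * dens + 1.0
        exact = (vals[0] + vals[-1]) / 2 * 0.40
        assert np.trapezoid(vals, dens) == pytest.approx(exact)

    def test_invalid_grids(self, conn10):
        with pytest.raises(ValueError):
            auc_over_densities(conn10, densities=[0.2])
        with pytest.raises(ValueError):
            auc_over_densities(conn10, densities=[0.3, 0.2, 0.4])
        with pytest.raises(ValueError):
            auc_over_densities(conn10, measure="bogus")

    def test_model_results_match_function(self, conn10):
        res = CommunicationModel(conn10).fit()
        assert res.auc_e_nav == pytest.approx(auc_over_densities(conn10, measure="e_nav"))
        assert res.auc_e_sp == pytest.approx(auc_over_densities(conn10, measure="e_sp"))
        assert (res.per_density["e_sp"] >= res.per_density["e_nav"] - 1e-9).all()


class TestGeometry:
    def test_3_4_5(self):
        d = euclidean_matrix(np.array([[0, 0, 0], [3.0, 4.0, 0]]))
        assert d[0, 1] == 5.0 and d[0, 0] == 0.0

    def test_triangle_inequality(self):
        coords = np.random.default_rng(12).uniform(-10, 10, (6, 3))
        d = euclidean_matrix(coords)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestRegionToLesionDistance:
    def test_zero_at_own_center(self, regions6):
        rid = int(regions6[regions6["hemisphere"] == "right"]["region_id"].iloc[0])
        com = tuple(regions6.loc[rid, ["x", "y", "z"]])
        s = SubjectRecord("S1", "stroke", lesion_centroids=[com],
                          lesion_side="right", lesion_regions={rid})
        d = region_to_lesion_distance(regions6, s)
        assert d.loc[rid] == pytest.approx(0.0)

    def test_minimum_over_multiple_lesions(self, regions6):
        rid = int(regions6[regions6["hemisphere"] == "right"]["region_id"].iloc[0])
        com = regions6.loc[rid, ["x", "y", "z"]].to_numpy(dtype=float)
        near = tuple(com + [1.0, 0, 0])
        far = tuple(com + [50.0, 0, 0])
        s = SubjectRecord("S1", "stroke", lesion_centroids=[far, near],
                          lesion_side="right", lesion_regions={rid})
        d = region_to_lesion_distance(regions6, s)
        assert d.loc[rid] == pytest.approx(1.0)

    def test_uses_ipsilesional_com_only(self, regions6):
        # lesion on the left: distances computed from left-hemisphere coords
        pair = regions6[regions6["hemisphere"] == "right"].iloc[0]
        rid, lid = int(pair["region_id"]), int(pair["homotopic_partner"])
        left_com = tuple(regions6.loc[lid, ["x", "y", "z"]])
        s = SubjectRecord("S1", "stroke", lesion_centroids=[left_com],
                          lesion_side="left", lesion_regions={lid})
        d = region_to_lesion_distance(regions6, s)
        assert d.loc[rid] == pytest.approx(0.0)

    def test_control_rejected(self, regions6):
        with pytest.raises(ValueError):
            region_to_lesion_distance(regions6, SubjectRecord("C1", "control"))
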