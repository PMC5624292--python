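import numpy as np
import pytest
from scipy import sparse

from landgen.geo import haversine
from landgen.graph import (GraphError, TransitionGraph, UnreachableError,
                           build_transition, commute_distance, geo_correct,
                           least_cost_distance, shortest_path)
from landgen.raster import LandscapeRaster
from oracles import (commute_pinv, effective_resistance_pinv,
                     enumerate_simple_paths_cost, relaxation_shortest_paths)


def conductance_raster(values, dx=0.01, dy=0.01, lat=-39.9):
    return LandscapeRaster(np.asarray(values, dtype=float), xll=-73.0,
                           yll=lat, dx=dx, dy=dy, semantics="conductance")


def unit_graph(values):
    """Planar-corrected graph on a unit grid (dx = dy = 1 degree treated
    as unit spacing), so costs are in plain cell units."""
    r = LandscapeRaster(np.asarray(values, dtype=float), xll=0.0, yll=0.0,
                        dx=1.0, dy=1.0, semantics="conductance")
    return geo_correct(build_transition(r), "planar")


class TestBuildTransition:
    def test_two_cell_edge_is_arithmetic_mean(self):
        g = build_transition(conductance_raster([[1.0, 3.0]]))
        assert g.matrix[0, 1] == pytest.approx(2.0)
        assert g.matrix[1, 0] == pytest.approx(2.0)

    def test_geometric_mean_option(self):
        g = build_transition(conductance_raster([[1.0, 4.0]]),
                             mean="geometric")
        assert g.matrix[0, 1] == pytest.approx(2.0)

    def test_uniform_grid_unit_edges(self):
        g = build_transition(conductance_raster(np.ones((3, 3))))
        assert np.allclose(g.matrix.data, 1.0)

    def test_interior_cell_has_eight_edges(self):
        g = build_transition(conductance_raster(np.ones((3, 3))))
        centre = 4  # row 1, col 1
        assert g.matrix[centre].getnnz() == 8

    def test_zero_conductance_cell_isolated(self):
        vals = np.ones((3, 3))
        vals[1, 1] = 0.0
        g = build_transition(conductance_raster(vals))
        assert g.matrix[4].getnnz() == 0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        g = build_transition(conductance_raster(rng.uniform(0.1, 2, (4, 5))))
        M = g.matrix.todense()
        assert np.allclose(M, M.T)
        assert np.all(np.diag(M) == 0)


class TestGeoCorrect:
    def test_lcp_diagonal_edges_weaker_than_orthogonal(self):
        g = geo_correct(build_transition(conductance_raster(np.ones((3, 3)))),
                        "lcp")
        orth = g.matrix[4, 1]   # centre to north neighbour
        diag = g.matrix[4, 0]   # centre to NW neighbour
        assert diag < orth

    def test_lcp_divides_by_great_circle_distance(self):
        r = conductance_raster([[1.0, 1.0]])
        g = geo_correct(build_transition(r), "lcp")
        lon0, lat0 = r.cell_center(0, 0)
        lon1, lat1 = r.cell_center(0, 1)
        assert g.matrix[0, 1] == pytest.approx(
            1.0 / haversine(lon0, lat0, lon1, lat1))

    def test_ibr_at_equator_leaves_ns_edges_unchanged(self):
        r = conductance_raster(np.ones((2, 1)), lat=-0.01)  # centres at lat 0
        g = geo_correct(build_transition(r), "ibr")
        assert g.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_ibr_at_lat_sixty_halves_ns_edges(self):
        r = conductance_raster(np.ones((2, 1)), lat=59.99)
        g = geo_correct(build_transition(r), "ibr")
        assert g.matrix[0, 1] == pytest.approx(0.5, abs=1e-3)

    def test_ibr_leaves_ew_edges_unchanged(self):
        r = conductance_raster(np.ones((1, 2)), lat=59.99)
        g = geo_correct(build_transition(r), "ibr")
        assert g.matrix[0, 1] == pytest.approx(1.0)

    def test_double_correction_rejected(self):
        g = geo_correct(build_transition(conductance_raster(np.ones((2, 2)))),
                        "lcp")
        with pytest.raises(GraphError, match="already"):
            geo_correct(g, "ibr")


class TestLeastCost:
    def test_straight_row_cost_equals_steps(self):
        g = unit_graph(np.ones((1, 4)))
        D = least_cost_distance(g, [0, 3])
        assert D[0, 1] == pytest.approx(3.0)

    def test_three_by_three_corner_to_corner_diagonal(self):
        g = unit_graph(np.ones((3, 3)))
        D = least_cost_distance(g, [0, 8])
        assert D[0, 1] == pytest.approx(2 * np.sqrt(2))

    def test_matches_complete_path_enumeration_small(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            vals = rng.uniform(0.2, 2.0, (3, 3))
            g = unit_graph(vals)
            cost = g.matrix.copy()  # weights; oracle takes 1/w costs below
            D = least_cost_distance(g, [0, 8])
            assert D[0, 1] == pytest.approx(
                enumerate_simple_paths_cost(g.matrix, 0, 8), rel=1e-10)

    def test_barrier_forces_route_through_gap(self):
        vals = np.ones((5, 5))
        vals[2, :] = 0.0
        vals[2, 4] = 1.0  # single gap in the barrier row
        g = unit_graph(vals)
        D = least_cost_distance(g, [0, 20])  # NW corner to SW corner
        oracle = relaxation_shortest_paths(g.matrix)
        assert D[0, 1] == pytest.approx(oracle[0, 20], rel=1e-10)
        assert D[0, 1] > 4.0  # longer than the blocked straight column

    def test_unreachable_strict_raises_lenient_inf(self):
        vals = np.ones((1, 3))
        vals[0, 1] = 0.0
        g = unit_graph(vals)
        with pytest.raises(UnreachableError):
            least_cost_distance(g, [0, 2])
        with pytest.warns(UserWarning):
            D = least_cost_distance(g, [0, 2], strict=False)
        assert np.isinf(D[0, 1])

    def test_triangle_inequality_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = unit_graph(rng.uniform(0.1, 3.0, (4, 4)))
            cells = rng.choice(16, size=4, replace=False)
            D = least_cost_distance(g, cells)
            for a in range(4):
                for b in range(4):
                    for c in range(4):
                        assert D[a, b] <= D[a, c] + D[c, b] + 1e-9


class TestCommute:
    def test_two_node_commute_is_two_steps_any_weight(self):
        for w in (0.1, 1.0, 7.3):
            g = TransitionGraph.from_matrix([[0, w], [w, 0]])
            C = commute_distance(g, [0, 1])
            assert C[0, 1] == pytest.approx(2.0)

    def test_three_node_path_ends_eight_steps(self):
        W = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        g = TransitionGraph.from_matrix(W)
        C = commute_distance(g, [0, 2])
        assert C[0, 1] == pytest.approx(8.0)
        assert C[0, 1] == pytest.approx(commute_pinv(np.asarray(W))[0, 2])

    def test_series_rule_on_path_graphs(self):
        # resistances add in series: R(0,k) = sum 1/w_i
        rng = np.random.default_rng(5)
        w = rng.uniform(0.5, 3.0, size=4)
        W = np.zeros((5, 5))
        for i, wi in enumerate(w):
            W[i, i + 1] = W[i + 1, i] = wi
        g = TransitionGraph.from_matrix(W)
        C = commute_distance(g, [0, 4])
        r_expected = np.sum(1.0 / w)
        assert C[0, 1] == pytest.approx(W.sum() * r_expected)

    def test_parallel_rule(self):
        # two unit edges in parallel behave as one edge of weight 2
        g = TransitionGraph.from_matrix([[0, 2.0], [2.0, 0]])
        C = commute_distance(g, [0, 1])
        assert C[0, 1] == pytest.approx(2.0)  # vol 4, R 1/2

    def test_matches_pseudoinverse_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 7
            W = np.triu(rng.uniform(0, 1, (n, n)) *
                        (rng.uniform(size=(n, n)) < 0.6), 1)
            W = W + W.T
            if not np.isfinite(effective_resistance_pinv(W)).all():
                continue
            g = TransitionGraph.from_matrix(W)
            cells = [0, n // 2, n - 1]
            try:
                C = commute_distance(g, cells)
            except UnreachableError:
                continue
            oracle = commute_pinv(W)
            for a, ca in enumerate(cells):
                for b, cb in enumerate(cells):
                    if np.isfinite(C[a, b]):
                        assert C[a, b] == pytest.approx(oracle[ca, cb],
                                                        rel=1e-8)

    def test_extra_edge_never_increases_commute(self):
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        base_R = effective_resistance_pinv(W)
        g1 = TransitionGraph.from_matrix(W)
        R1 = commute_distance(g1, [0, 3])[0, 1] / W.sum()
        W2 = W.copy()
        W2[0, 3] = W2[3, 0] = 0.5
        R2 = commute_distance(TransitionGraph.from_matrix(W2), [0, 3])[0, 1] \
            / W2.sum()
        assert R2 <= R1 + 1e-12
        assert R1 == pytest.approx(base_R[0, 3])

    def test_disconnected_pair_strict_raises(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        g = TransitionGraph.from_matrix(W)
        with pytest.raises(UnreachableError):
            commute_distance(g, [0, 2])


class TestMonotonicityAndScaling:
    def test_raising_conductance_never_increases_distances(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(0.2, 1.0, (4, 4))
        g = unit_graph(vals)
        D0 = least_cost_distance(g, [0, 15])
        R0 = effective_resistance_pinv(g.matrix.todense())
        for _ in range(10):
            vals2 = vals.copy()
            i, j = rng.integers(4), rng.integers(4)
            vals2[i, j] *= 1.0 + rng.uniform(0.1, 2.0)
            g2 = unit_graph(vals2)
            D1 = least_cost_distance(g2, [0, 15])
            R1 = effective_resistance_pinv(g2.matrix.todense())
            assert D1[0, 1] <= D0[0, 1] + 1e-9
            assert R1[0, 15] <= R0[0, 15] + 1e-9

    def test_conductance_scaling_rescales_distances_reciprocally(self):
        rng = np.random.default_rng(21)
        vals = rng.uniform(0.3, 2.0, (4, 4))
        c = 3.7
        g1 = unit_graph(vals)
        g2 = unit_graph(vals * c)
        cells = [0, 5, 15]
        D1 = least_cost_distance(g1, cells)
        D2 = least_cost_distance(g2, cells)
        assert np.allclose(D2, D1 / c)
        R1 = effective_resistance_pinv(g1.matrix.todense())
        R2 = effective_resistance_pinv(g2.matrix.todense())
        assert np.allclose(R2, R1 / c)


class TestShortestPath:
    def test_origin_equals_destination(self):
        g = unit_graph(np.ones((2, 2)))
        p = shortest_path(g, 1, 1)
        assert p.cells == [1] and p.cost == 0.0

    def test_uniform_surface_path_is_diagonal(self):
        g = unit_graph(np.ones((4, 4)))
        p = shortest_path(g, 0, 15)
        assert len(p.cells) == 4  # pure diagonal: 0, 5, 10, 15
        assert p.cost == pytest.approx(3 * np.sqrt(2))

    def test_consecutive_cells_are_neighbours(self):
        rng = np.random.default_rng(2)
        g = unit_graph(rng.uniform(0.2, 2.0, (5, 5)))
        p = shortest_path(g, 0, 24)
        for a, b in zip(p.cells[:-1], p.cells[1:]):
            ra, ca = divmod(a, 5)
            rb, cb = divmod(b, 5)
            assert max(abs(ra - rb), abs(ca - cb)) == 1

    def test_corridor_dominates_class_composition(self):
        classes = np.full((5, 7), 2)
        classes[2, :] = 1  # single high-conductance corridor row
        class_raster = LandscapeRaster(classes, xll=0.0, yll=0.0, dx=1.0,
                                       dy=1.0, semantics="classes")
        cond = np.where(classes == 1, 1.0, 0.05)
        g = unit_graph(cond)
        p = shortest_path(g, 2 * 7 + 0, 2 * 7 + 6, class_raster)
        assert p.class_composition[1] > 0.9

    def test_unreachable_raises(self):
        vals = np.ones((1, 3))
        vals[0, 1] = 0.0
        g = unit_graph(vals)
        with pytest.raises(UnreachableError):
            shortest_path(g, 0, 2)
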