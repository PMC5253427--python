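"""Euclidean, least-cost-path and barrier-count distance operations."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from landgenkit.core_data import BarrierSet, ResistanceSurface
from landgenkit.errors import ValidationError
from landgenkit.landscape_distance import (
    barrier_count_matrix,
    euclidean_matrix,
    lcp_matrix,
)

from conftest import build_table


def table_at(points):
    return build_table([[(1, 1)] for _ in points], coords=points)


class TestEuclidean:
    def test_three_four_five(self):
        t = table_at([(0.0, 0.0), (3.0, 4.0)])
        d = euclidean_matrix(t)
        assert d.values[0, 1] == pytest.approx(5.0, abs=1e-12)
        dl = euclidean_matrix(t, log_transform=True)
        assert dl.values[0, 1] == pytest.approx(np.log(5.0), abs=1e-12)
        assert dl.values[0, 0] == 0.0

    def test_isometry_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2)) * 100
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([123.0, -456.0])
        d1 = euclidean_matrix(table_at([tuple(p) for p in pts]))
        d2 = euclidean_matrix(table_at([tuple(p) for p in moved]))
        assert np.allclose(d1.values, d2.values, atol=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1000, size=(20, 2))
        d = euclidean_matrix(table_at([tuple(p) for p in pts]))
        for i in range(20):
            for j in range(20):
                expected = np.sqrt(
                    (pts[i, 0] - pts[j, 0]) ** 2 + (pts[i, 1] - pts[j, 1]) ** 2
                )
                assert d.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_coincident_pair_with_log_is_error(self):
        t = table_at([(1.0, 1.0), (1.0, 1.0)])
        with pytest.raises(ValidationError, match="coincident"):
            euclidean_matrix(t, log_transform=True)


def _networkx_lcp_oracle(surface, cells_a, cells_b):
    """Independent Dijkstra on an explicit edge list (networkx)."""
    import networkx as nx

    nr, nc = surface.n_rows, surface.n_cols
    G = nx.Graph()
    for r in range(nr):
        for c in range(nc):
            if surface.nodata_mask[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc and not surface.nodata_mask[r2, c2]:
                    w = (
                        0.5
                        * (surface.values[r, c] + surface.values[r2, c2])
                        * surface.cell_size
                        * (np.sqrt(2.0) if dr and dc else 1.0)
                    )
                    G.add_edge((r, c), (r2, c2), weight=w)
    return nx.shortest_path_length(G, cells_a, cells_b, weight="weight")


class TestLcp:
    def test_uniform_corridor(self):
        s = ResistanceSurface(np.ones((1, 11)), cell_size=30.0, origin_x=0, origin_y=0)
        t = table_at([(15.0, 15.0), (315.0, 15.0)])
        res = lcp_matrix(t, s)
        assert res.matrix.values[0, 1] == pytest.approx(300.0, abs=1e-9)

    def test_wall_with_gap_matches_networkx_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.5, 5.0, size=(5, 5))
        mask = np.zeros((5, 5), dtype=bool)
        mask[:, 2] = True
        mask[2, 2] = False  # single gap
        s = ResistanceSurface(
            np.where(mask, np.nan, vals), cell_size=10.0, origin_x=0, origin_y=0,
            nodata_mask=mask,
        )
        t = table_at([(5.0, 45.0), (45.0, 5.0)])  # opposite corners
        res = lcp_matrix(t, s)
        ca = s.cell_of(5.0, 45.0)
        cb = s.cell_of(45.0, 5.0)
        expected = _networkx_lcp_oracle(s, ca, cb)
        assert res.matrix.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_doubling_costs_doubles_lcp(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1.0, 4.0, size=(8, 8))
        pts = [(5.0, 5.0), (75.0, 75.0), (35.0, 60.0)]
        s1 = ResistanceSurface(vals, cell_size=10.0, origin_x=0, origin_y=0)
        s2 = ResistanceSurface(2 * vals, cell_size=10.0, origin_x=0, origin_y=0)
        m1 = lcp_matrix(table_at(pts), s1).matrix.values
        m2 = lcp_matrix(table_at(pts), s2).matrix.values
        assert np.allclose(m2, 2 * m1, atol=1e-9)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0.5, 6.0, size=(12, 12))
        s = ResistanceSurface(vals, cell_size=10.0, origin_x=0, origin_y=0)
        pts = [tuple(p) for p in rng.uniform(3, 117, size=(10, 2))]
        m = lcp_matrix(table_at(pts), s).matrix.values
        n = len(pts)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_uniform_surface_lattice_bound(self):
        s = ResistanceSurface(np.full((30, 30), 2.5), cell_size=10.0, origin_x=0, origin_y=0)
        rng = np.random.default_rng(6)
        pts = [tuple(p) for p in rng.uniform(5, 295, size=(8, 2))]
        t = table_at(pts)
        lcp = lcp_matrix(t, s).matrix.values
        # compare against cost x distance between the snapped cell centers
        centers = np.array([s.center_of(*s.cell_of(x, y)) for x, y in pts])
        eu = np.hypot(
            centers[:, None, 0] - centers[None, :, 0],
            centers[:, None, 1] - centers[None, :, 1],
        )
        off = ~np.eye(len(pts), dtype=bool)
        ratio = lcp[off] / (2.5 * eu[off])
        assert (ratio >= 1.0 - 1e-9).all()
        assert (ratio <= 1.0824 + 1e-9).all()

    def test_individual_on_masked_cell_is_error(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        s = ResistanceSurface(
            np.where(mask, np.nan, 1.0), cell_size=10.0, origin_x=0, origin_y=0,
            nodata_mask=mask,
        )
        t = table_at([(5.0, 15.0), (15.0, 5.0)])
        with pytest.raises(ValidationError, match="NODATA"):
            lcp_matrix(t, s)

    def test_disconnected_pair_flagged_nan(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, 1] = True  # full wall
        s = ResistanceSurface(
            np.where(mask, np.nan, 1.0), cell_size=10.0, origin_x=0, origin_y=0,
            nodata_mask=mask,
        )
        t = table_at([(5.0, 15.0), (25.0, 15.0)])
        res = lcp_matrix(t, s)
        assert np.isnan(res.matrix.values[0, 1])
        assert res.n_disconnected_pairs == 1


class TestBarrierCount:
    def test_single_road_crossing(self):
        b = BarrierSet([LineString([(5.0, -10.0), (5.0, 10.0)])], "roads")
        t = table_at([(0.0, 0.0), (10.0, 0.0)])
        m = barrier_count_matrix(t, b)
        assert m.values[0, 1] == 1.0

    def test_no_features_all_zero(self):
        b = BarrierSet([], "cutblocks")
        t = table_at([(0.0, 0.0), (10.0, 0.0), (3.0, 9.0)])
        assert (barrier_count_matrix(t, b).values == 0).all()

    def test_fence_of_seven_lines(self):
        feats = [LineString([(x, -5.0), (x, 5.0)]) for x in np.linspace(1, 9, 7)]
        b = BarrierSet(feats, "linear_features")
        t = table_at([(0.0, 0.0), (10.0, 0.0)])
        assert barrier_count_matrix(t, b).values[0, 1] == 7.0

    def test_matches_segment_intersection_oracle(self):
        rng = np.random.default_rng(13)
        feats = [
            LineString(rng.uniform(0, 100, size=(3, 2)).tolist()) for _ in range(6)
        ]
        b = BarrierSet(feats, "roads")
        pts = [tuple(p) for p in rng.uniform(0, 100, size=(6, 2))]
        t = table_at(pts)
        m = barrier_count_matrix(t, b).values
        for i in range(6):
            for j in range(i + 1, 6):
                seg = LineString([pts[i], pts[j]])
                expected = sum(1 for f in feats if f.intersects(seg))
                assert m[i, j] == expected

    def test_winding_feature_counts_once(self):
        # one polyline crossing the segment twice still counts as one barrier
        wiggle = LineString([(3.0, -5.0), (3.0, 5.0), (6.0, 5.0), (6.0, -5.0)])
        b = BarrierSet([wiggle], "roads")
        t = table_at([(0.0, 0.0), (10.0, 0.0)])
        assert barrier_count_matrix(t, b).values[0, 1] == 1.0

    def test_polygon_interior_counts(self):
        square = Polygon([(4, -2), (6, -2), (6, 2), (4, 2)])
        b = BarrierSet([square], "cutblocks")
        t = table_at([(0.0, 0.0), (10.0, 0.0)])
        assert barrier_count_matrix(t, b).values[0, 1] == 1.0

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(1)
        feats = [LineString(rng.uniform(0, 50, size=(2, 2)).tolist()) for _ in range(5)]
        pts = [tuple(p) for p in rng.uniform(0, 50, size=(4, 2))]
        t = table_at(pts)
        m1 = barrier_count_matrix(t, BarrierSet(feats, "roads")).values
        m2 = barrier_count_matrix(t, BarrierSet(feats[::-1], "roads")).values
        assert np.array_equal(m1, m2)
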