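"""Delaunay neighbors, lip distances and the overlapping-window scheme."""

import itertools

import numpy as np
import pytest

from gastrumorph import (AnalysisConfig, RegionAnnotation, ValidationError,
                         delaunay_graph, distance_to_lip,
                         mean_neighbor_distance, windowed_neighbor_stats)
from gastrumorph.spatial import PointCloud
from gastrumorph.synthetic import CloudParams, gen_point_cloud, straight_lip


def cloud(points):
    pts = np.asarray(points, dtype=float)
    return PointCloud(ids=list(range(len(pts))), points=pts)


def brute_force_delaunay_edges(points: np.ndarray) -> set:
    """All edges of empty-circumcircle triangles (O(n^4) oracle).

    Independent of any triangulation library: a triangle is Delaunay iff
    no other point lies strictly inside its circumcircle; the Delaunay
    edge set of a general-position point set is the union of edges of
    those triangles.
    """
    n = len(points)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = points[i], points[j], points[k]
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area2) < 1e-12:
            continue
        # circumcenter by solving the perpendicular-bisector equations
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1])
                 + c[0] * (a[1] - b[1]))
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1])
              + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0])
              + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        r2 = float((a - center) @ (a - center))
        empty = all(float((points[m] - center) @ (points[m] - center))
                    >= r2 * (1 - 1e-9)
                    for m in range(n) if m not in (i, j, k))
        if empty:
            edges.update({tuple(sorted(p)) for p in
                          [(i, j), (j, k), (i, k)]})
    return edges


class TestDelaunayGraph:
    def test_triangle_is_complete(self):
        g = delaunay_graph(cloud([(0, 0), (1, 0), (0, 1)]))
        assert g.edges == {(0, 1), (0, 2), (1, 2)}

    def test_unit_square_has_one_diagonal(self):
        pts = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        g = delaunay_graph(cloud(pts))
        diagonals = {(0, 2), (1, 3)}
        assert len(g.edges) == 5
        assert len(g.edges & diagonals) == 1
        # matches the brute-force empty-circumcircle edges (the cocircular
        # square admits either diagonal; the oracle reports both)
        assert g.edges <= brute_force_delaunay_edges(pts)

    def test_collinear_rejected(self):
        with pytest.raises(ValidationError, match="collinear"):
            delaunay_graph(cloud([(0, 0), (1, 0), (2, 0), (3, 0)]))

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for trial in range(40):
            n = int(rng.integers(4, 16))
            pts = rng.uniform(0, 100, size=(n, 2))
            g = delaunay_graph(cloud(pts))
            assert g.edges == brute_force_delaunay_edges(pts), \
                f"trial {trial}, n={n}"

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, size=(30, 2))
        g1 = delaunay_graph(cloud(pts))
        g2 = delaunay_graph(cloud(pts))
        assert g1.edges == g2.edges


class TestMeanNeighborDistance:
    def test_equilateral_triangle(self):
        pts = [(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)]
        c = cloud(pts)
        nn = mean_neighbor_distance(c, delaunay_graph(c))
        np.testing.assert_allclose(nn, [1.0, 1.0, 1.0], rtol=1e-12)

    def test_unit_square_corner_on_diagonal(self):
        pts = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        c = cloud(pts)
        g = delaunay_graph(c)
        nn = mean_neighbor_distance(c, g)
        (diag,) = g.edges & {(0, 2), (1, 3)}
        expected_on_diag = (1 + 1 + np.sqrt(2)) / 3
        for idx in diag:
            assert nn[idx] == pytest.approx(expected_on_diag)

    def test_hexagonal_interior_equals_spacing(self, lip):
        c = gen_point_cloud(CloudParams(spacing=lambda d: 10.0), lip)
        g = delaunay_graph(c)
        nn = mean_neighbor_distance(c, g, exclude_hull=True)
        interior = nn[np.isfinite(nn)]
        assert interior.size > 100
        np.testing.assert_allclose(interior, 10.0, rtol=1e-9)

    def test_scales_linearly_and_rigid_invariant(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(20, 2))
        c0 = cloud(pts)
        nn0 = mean_neighbor_distance(c0, delaunay_graph(c0))
        a = 0.7
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        c1 = cloud(pts @ rot.T + [5, -3])
        nn1 = mean_neighbor_distance(c1, delaunay_graph(c1))
        np.testing.assert_allclose(nn1, nn0, rtol=1e-9)
        c2 = cloud(pts * 3.0)
        nn2 = mean_neighbor_distance(c2, delaunay_graph(c2))
        np.testing.assert_allclose(nn2, 3.0 * nn0, rtol=1e-9)


class TestDistanceToLip:
    segment = RegionAnnotation("lip", "polyline",
                               np.array([[-10.0, 0.0], [10.0, 0.0]]))

    def test_perpendicular_distance(self):
        assert distance_to_lip((0, 5), self.segment) == pytest.approx(5.0)

    def test_clamped_to_endpoint(self):
        assert distance_to_lip((15, 0), self.segment) == pytest.approx(5.0)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(9)
        verts = np.cumsum(rng.uniform(-5, 5, size=(21, 2)), axis=0)
        line = RegionAnnotation("lip", "polyline", verts)
        # oracle: minimum distance to densely interpolated curve points
        dense = []
        for a, b in zip(verts[:-1], verts[1:]):
            ts = np.linspace(0, 1, 2000)[:, None]
            dense.append(a + ts * (b - a))
        dense = np.vstack(dense)
        for _ in range(20):
            p = rng.uniform(-30, 30, size=2)
            brute = float(np.min(np.linalg.norm(dense - p, axis=1)))
            assert distance_to_lip(p, line) == pytest.approx(brute, abs=1e-4)


class TestWindowedStats:
    def test_single_window_population(self):
        stats = windowed_neighbor_stats(np.full(11, 7.0), np.full(11, 10.0))
        assert stats[0].d_lo == 0.0 and stats[0].d_hi == 30.0
        assert stats[0].n == 11 and stats[0].mean == 7.0
        assert all(w.n == 0 for w in stats[1:])

    def test_overlap_strip_counted_twice(self):
        stats = windowed_neighbor_stats(np.array([5.0]), np.array([27.0]),
                                        max_distance=60.0)
        in_windows = [(w.d_lo, w.d_hi) for w in stats if w.n == 1]
        assert in_windows == [(0.0, 30.0), (25.0, 55.0)]

    def test_window_scheme_boundaries(self, config):
        stats = windowed_neighbor_stats(np.zeros(1), np.zeros(1),
                                        max_distance=100.0)
        bounds = [(w.d_lo, w.d_hi) for w in stats]
        assert bounds[:4] == [(0.0, 30.0), (25.0, 55.0), (50.0, 80.0),
                              (75.0, 105.0)]
        for w in stats:
            assert w.d_hi - w.d_lo == config.window_width

    def test_membership_counts_at_least_cover(self):
        rng = np.random.default_rng(2)
        lipd = rng.uniform(0, 100, size=200)
        vals = rng.uniform(5, 15, size=200)
        stats = windowed_neighbor_stats(vals, lipd)
        covered = ((lipd >= 0) & (lipd < stats[-1].d_hi)).sum()
        assert sum(w.n for w in stats) >= covered

    def test_two_spacing_cloud_recovers_both_spacings(self, lip):
        params = CloudParams(
            spacing=lambda d: 6.0 if d < 30.0 else 10.0, depth=130.0)
        c = gen_point_cloud(params, lip)
        from gastrumorph.spatial import distances_to_lip
        g = delaunay_graph(c)
        nn = mean_neighbor_distance(c, g, exclude_hull=True)
        lipd = distances_to_lip(c.points, lip)
        stats = windowed_neighbor_stats(nn, lipd)
        near = stats[0]    # [0, 30)
        far = stats[2]     # [50, 80)
        assert near.mean == pytest.approx(6.0, rel=0.05)
        assert far.mean == pytest.approx(10.0, rel=0.05)
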