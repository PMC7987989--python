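"""Spatial organization of nuclei: Delaunay neighbors, lip distance, windows.

At a chosen time point the nucleus centers are triangulated (Delaunay), each
nucleus' mean Euclidean distance to its Delaunay neighbors is computed, and
nuclei are stratified by their distance to a manually annotated blastopore
lip curve into overlapping windows (width 30 um, step 25 um, so consecutive
windows share a 5 um strip).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point

from .io import AnalysisConfig, RegionAnnotation, TrackTable, ValidationError

__all__ = [
    "PointCloud",
    "NeighborGraph",
    "WindowedStat",
    "delaunay_graph",
    "mean_neighbor_distance",
    "distance_to_lip",
    "windowed_neighbor_stats",
    "cloud_from_table",
]


@dataclass
class PointCloud:
    """Nucleus centers at a single time point."""

    ids: list
    points: np.ndarray  # (n, 2) um
    frame: Optional[int] = None
    t: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must be (n, 2)")
        if len(self.ids) != len(self.points):
            raise ValidationError("ids/points length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("point ids must be unique")


@dataclass
class NeighborGraph:
    """Symmetric Delaunay adjacency over a point cloud."""

    edges: set[tuple[int, int]]         # index pairs (i < j)
    neighbors: list[list[int]]          # per point, sorted neighbor indices
    hull: np.ndarray                    # indices of convex-hull points

    @property
    def n_points(self) -> int:
        return len(self.neighbors)


def delaunay_graph(cloud: PointCloud) -> NeighborGraph:
    """Delaunay triangulation adjacency (empty-circumcircle neighbors).

    Requires >= 3 non-collinear points.  For cocircular degeneracies the
    triangulation is resolved deterministically for a fixed input order, so
    repeated runs give the same graph.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise ValidationError("need >= 3 points for a triangulation")
    centered = pts - pts.mean(axis=0)
    # collinearity: rank of the centered coordinates
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValidationError("all points are collinear; no triangulation")
    tri = Delaunay(pts)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    neighbors: list[list[int]] = [[] for _ in range(len(pts))]
    for i, j in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    neighbors = [sorted(ns) for ns in neighbors]
    hull = np.unique(tri.convex_hull.ravel())
    return NeighborGraph(edges=edges, neighbors=neighbors, hull=hull)


def mean_neighbor_distance(cloud: PointCloud, graph: NeighborGraph,
                           exclude_hull: bool = False) -> np.ndarray:
    """Per-point mean Euclidean distance to its Delaunay neighbors (um).

    Convex-hull points have truncated neighborhoods; with ``exclude_hull``
    their entry is NaN so downstream summaries can drop them.
    """
    if graph.n_points != len(cloud.points):
        raise ValidationError("graph does not match cloud")
    out = np.empty(len(cloud.points))
    for i, ns in enumerate(graph.neighbors):
        if not ns:
            raise ValidationError(f"point {i} is isolated")
        d = np.linalg.norm(cloud.points[ns] - cloud.points[i], axis=1)
        out[i] = d.mean()
    if exclude_hull:
        out[graph.hull] = np.nan
    return out


def distance_to_lip(point: Sequence[float], lip: RegionAnnotation) -> float:
    """Closest Euclidean distance from a point to the lip polyline (um)."""
    if lip.kind != "polyline" or len(lip.vertices) < 2:
        raise ValidationError("lip must be a polyline with >= 2 vertices")
    return float(LineString(lip.vertices).distance(Point(point[0], point[1])))


def distances_to_lip(points: np.ndarray, lip: RegionAnnotation) -> np.ndarray:
    line = LineString(lip.vertices)
    return np.array([line.distance(Point(p[0], p[1])) for p in points])


@dataclass
class WindowedStat:
    d_lo: float
    d_hi: float
    n: int
    mean: float  # NaN when the window is empty
    sd: float    # NaN when n < 2


def windowed_neighbor_stats(percell: np.ndarray, lipdist: np.ndarray,
                            config: Optional[AnalysisConfig] = None,
                            max_distance: Optional[float] = None,
                            ) -> list[WindowedStat]:
    """Stratify per-cell values into overlapping lip-distance windows.

    Windows are [0, 30), [25, 55), [50, 80), ... by default: width 30 um,
    step 25 um, so consecutive windows overlap by 5 um and a cell in the
    overlap strip is counted in both.  NaN values (e.g. excluded hull
    points) are dropped per window.
    """
    config = config or AnalysisConfig()
    percell = np.asarray(percell, dtype=float)
    lipdist = np.asarray(lipdist, dtype=float)
    if percell.shape != lipdist.shape:
        raise ValidationError("percell and lipdist must have equal length")
    if max_distance is None:
        max_distance = float(lipdist.max()) if lipdist.size else 0.0
    out = []
    lo = 0.0
    while lo < max_distance or lo == 0.0:
        hi = lo + config.window_width
        mask = (lipdist >= lo) & (lipdist < hi) & np.isfinite(percell)
        vals = percell[mask]
        out.append(WindowedStat(
            d_lo=lo, d_hi=hi, n=int(mask.sum()),
            mean=float(vals.mean()) if vals.size else float("nan"),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        ))
        lo += config.window_step
    return out


def windows_to_frame(stats: Sequence[WindowedStat]) -> pd.DataFrame:
    return pd.DataFrame([{
        "d_lo_um": w.d_lo, "d_hi_um": w.d_hi, "n": w.n,
        "mean_um": w.mean, "sd_um": w.sd,
    } for w in stats])


def cloud_from_table(table: TrackTable, frame_time: float,
                     tolerance: Optional[float] = None) -> PointCloud:
    """Extract the nucleus point cloud at (the frame nearest to) a time point.

    Cells without a sample within ``tolerance`` minutes of ``frame_time``
    (default: half a frame interval) are omitted. z, when present, is
    dropped: the triangulation is planar.
    """
    if tolerance is None:
        tolerance = table.frame_interval / 2.0
    df = table.data
    dt = (df["t_min"] - frame_time).abs()
    near = df[dt <= tolerance + 1e-9].copy()
    # one sample per cell: the closest in time
    near["_dt"] = (near["t_min"] - frame_time).abs()
    near = near.sort_values("_dt", kind="stable").drop_duplicates("cell_id")
    ids = list(near["cell_id"])
    pts = near[["x_um", "y_um"]].to_numpy(dtype=float)
    return PointCloud(ids=ids, points=pts, t=frame_time)
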