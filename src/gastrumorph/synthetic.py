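"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis modules
assume — not the mechanics that produce it in an embryo:

* persistent random walks with tunable turning noise and drift toward a
  blastopore-lip curve (ground truth for persistence and velocity),
* hexagonal nucleus point clouds whose local spacing is a function of
  lip distance (ground truth for Delaunay neighbor distances),
* fields of elongated cells with controllable aspect ratio and orientation
  concentration about the mediolateral axis (ground truth for polarity and
  rose summaries),
* vegetal-view disk annotations with a shrinking blastopore (ground truth
  for the closure ratio),
* images with a straight fibril-like band (ground truth for the normalized
  intensity profile).

Every generator is a pure function of its parameters and seed; no global
random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .io import ImageLayer, RegionAnnotation, TrackTable, ValidationError
from .spatial import PointCloud
from .tracks import Trajectory

__all__ = [
    "WalkParams",
    "CloudParams",
    "MosaicParams",
    "gen_persistent_walk",
    "gen_track_dataset",
    "default_group_params",
    "gen_point_cloud",
    "gen_cell_mosaic",
    "gen_embryo_vegetal_view",
    "gen_fibril_image",
]


# ---------------------------------------------------------------------------
# Persistent random walks
# ---------------------------------------------------------------------------

@dataclass
class WalkParams:
    """Knobs of the persistent random walk.

    ``turning_sd`` is the standard deviation (degrees) of the wrapped
    Gaussian heading increment per frame; ``drift_weight`` in [0, 1] blends
    the noisy heading with the direction toward the nearest point of
    ``drift_target`` (0 = free walk, 1 = straight to the lip).
    """

    n_steps: int = 60
    step_length: float = 3.6          # um per frame
    turning_sd: float = 10.0          # degrees
    drift_target: Optional[RegionAnnotation] = None
    drift_weight: float = 0.0
    frame_interval: float = 3.0       # minutes
    seed: int = 0
    start: tuple[float, float] = (0.0, 0.0)
    initial_heading_deg: Optional[float] = None
    stop_distance: Optional[float] = None  # stop once this close to the lip

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.step_length < 0 or self.turning_sd < 0:
            raise ValidationError("step_length and turning_sd must be >= 0")
        if not (0.0 <= self.drift_weight <= 1.0):
            raise ValidationError("drift_weight must lie in [0, 1]")


def _toward(target: LineString, pos: np.ndarray) -> Optional[np.ndarray]:
    """Unit vector from pos toward the nearest point of the lip curve."""
    nearest = target.interpolate(target.project(Point(pos)))
    vec = np.array([nearest.x, nearest.y]) - pos
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return None
    return vec / norm


def gen_persistent_walk(params: WalkParams) -> Trajectory:
    """Simulate one persistent random walk; same params + seed, same walk."""
    rng = np.random.default_rng(params.seed)
    lip_line = (LineString(params.drift_target.vertices)
                if params.drift_target is not None else None)
    pos = np.asarray(params.start, dtype=float)
    if params.initial_heading_deg is not None:
        heading = math.radians(params.initial_heading_deg)
    elif lip_line is not None:
        d = _toward(lip_line, pos)
        heading = math.atan2(d[1], d[0]) if d is not None \
            else rng.uniform(-math.pi, math.pi)
    else:
        heading = rng.uniform(-math.pi, math.pi)

    points = [pos.copy()]
    sd_rad = math.radians(params.turning_sd)
    for _ in range(params.n_steps):
        heading = heading + rng.normal(0.0, sd_rad)
        if params.drift_weight > 0 and lip_line is not None:
            target = _toward(lip_line, pos)
            if target is not None:
                w = params.drift_weight
                vx = (1 - w) * math.cos(heading) + w * target[0]
                vy = (1 - w) * math.sin(heading) + w * target[1]
                if vx * vx + vy * vy > 1e-24:
                    heading = math.atan2(vy, vx)
        pos = pos + params.step_length * np.array(
            [math.cos(heading), math.sin(heading)])
        points.append(pos.copy())
        if (params.stop_distance is not None and lip_line is not None
                and lip_line.distance(Point(pos)) < params.stop_distance):
            break
    pts = np.asarray(points)
    times = params.frame_interval * np.arange(len(pts))
    return Trajectory(cell_id=None, times=times, positions=pts,
                      frames=np.arange(len(pts)))


def default_group_params() -> dict[str, WalkParams]:
    """The two synthetic conditions used throughout the package.

    Control-like cells walk fast, straight and strongly lip-directed;
    morphant-like cells walk slower, noisier and barely directed, mirroring
    the qualitative group differences the motility metrics are built to
    detect.
    """
    return {
        "control": WalkParams(n_steps=60, step_length=3.6, turning_sd=25.0,
                              drift_weight=0.30, stop_distance=5.0),
        "morphant": WalkParams(n_steps=60, step_length=2.4, turning_sd=30.0,
                               drift_weight=0.25, stop_distance=5.0),
    }


def gen_track_dataset(n_cells: int,
                      lip: RegionAnnotation,
                      params_by_group: Optional[dict[str, WalkParams]] = None,
                      seed: int = 0,
                      start_band: tuple[float, float] = (60.0, 130.0),
                      side: int = 1) -> TrackTable:
    """A multi-cell labeled TrackTable: ``n_cells`` walks per group.

    Each cell starts at a uniformly random arclength position along the lip,
    offset perpendicular to the local lip tangent by a uniform distance in
    ``start_band`` um on the chosen ``side``, and drifts back toward the
    lip according to its group's walk parameters.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if params_by_group is None:
        params_by_group = default_group_params()
    rng = np.random.default_rng(seed)
    line = LineString(lip.vertices)
    rows = []
    for group, base in params_by_group.items():
        for i in range(n_cells):
            s = rng.uniform(0.0, line.length)
            p0 = line.interpolate(s)
            p1 = line.interpolate(min(s + 1e-3, line.length))
            tang = np.array([p1.x - p0.x, p1.y - p0.y])
            tn = np.linalg.norm(tang)
            tang = tang / tn if tn > 0 else np.array([1.0, 0.0])
            normal = side * np.array([-tang[1], tang[0]])
            dist = rng.uniform(*start_band)
            start = np.array([p0.x, p0.y]) + dist * normal
            walk = replace(base, drift_target=lip,
                           seed=int(rng.integers(0, 2**31 - 1)),
                           start=(start[0], start[1]))
            traj = gen_persistent_walk(walk)
            cid = f"{group}_{i:04d}"
            for k in range(len(traj)):
                rows.append((cid, int(traj.frames[k]), traj.times[k],
                             traj.positions[k, 0], traj.positions[k, 1], group))
    df = pd.DataFrame(rows, columns=["cell_id", "frame", "t_min",
                                     "x_um", "y_um", "group"])
    first = next(iter(params_by_group.values()))
    return TrackTable(df, frame_interval=first.frame_interval).validate()


# ---------------------------------------------------------------------------
# Nucleus point clouds
# ---------------------------------------------------------------------------

@dataclass
class CloudParams:
    """Hexagonal nucleus lattice with lip-distance-dependent spacing.

    ``spacing`` maps distance-to-lip (um) to the local lattice constant
    (um); constant spacing with zero jitter gives an exact hexagonal
    lattice whose interior points all sit at that distance from each of
    their six Delaunay neighbors.
    """

    spacing: Callable[[float], float] = lambda d: 10.0
    width: float = 300.0     # extent along the lip, um
    depth: float = 150.0     # extent away from the lip, um
    jitter_sd: float = 0.0   # um
    seed: int = 0
    side: int = 1

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        if self.width <= 0 or self.depth <= 0:
            raise ValidationError("width and depth must be positive")


def gen_point_cloud(params: CloudParams, lip: RegionAnnotation) -> PointCloud:
    """Generate nuclei on a graded hexagonal lattice in a lip-aligned frame.

    The frame is anchored at the lip's first vertex with its x-axis along
    the straight first-to-last lip direction; rows of nuclei march away
    from the lip with local in-row spacing s(d) and row gap s(d)*sqrt(3)/2,
    alternate rows offset by half a spacing.  Where s(d) changes between
    rows the lattice has a seam; within a constant-spacing band it is exact.
    """
    v = lip.vertices
    u = v[-1] - v[0]
    un = np.linalg.norm(u)
    if un < 1e-12:
        raise ValidationError("lip endpoints coincide; no reference axis")
    u = u / un
    w = params.side * np.array([-u[1], u[0]])
    rng = np.random.default_rng(params.seed)

    pts = []
    d = params.spacing(0.0) / 2.0
    row = 0
    while d < params.depth:
        s = params.spacing(d)
        if s <= 0:
            raise ValidationError(f"spacing({d:.1f}) = {s} must be positive")
        x = (s / 2.0) if row % 2 else 0.0
        while x <= params.width:
            pts.append(v[0] + x * u + d * w)
            x += s
        d += s * math.sqrt(3.0) / 2.0
        row += 1
    pts = np.asarray(pts)
    if params.jitter_sd > 0:
        pts = pts + rng.normal(0.0, params.jitter_sd, size=pts.shape)
    return PointCloud(ids=list(range(len(pts))), points=pts)


# ---------------------------------------------------------------------------
# Cell mosaics
# ---------------------------------------------------------------------------

@dataclass
class MosaicParams:
    """Field of elongated cells about the mediolateral (x) axis.

    Orientations follow an axial von Mises law: phi ~ VM(0, kappa) on the
    doubled circle, cell orientation = phi / 2, so kappa = 0 is uniform in
    (-90, 90] and large kappa concentrates cells along the ML axis.
    """

    n_cells: int = 150
    mean_area: float = 400.0         # um^2
    aspect_ratio: float = 1.9        # target major/minor
    orientation_kappa: float = 8.0   # axial concentration about ML (x) axis
    image_shape: tuple[int, int] = (520, 520)  # pixels (rows, cols)
    pixel_size: float = 1.0          # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.aspect_ratio < 1:
            raise ValidationError("aspect_ratio must be >= 1")
        if self.orientation_kappa < 0:
            raise ValidationError("orientation_kappa must be >= 0")
        if self.mean_area <= 0 or self.pixel_size <= 0:
            raise ValidationError("mean_area and pixel_size must be positive")


def gen_cell_mosaic(params: MosaicParams) -> ImageLayer:
    """Rasterize non-overlapping elliptical cells on a jittered lattice.

    Each cell is an ellipse of area ``mean_area`` and axis ratio
    ``aspect_ratio`` at its sampled orientation, centered on a jittered
    square lattice whose pitch guarantees ellipses cannot collide; label 0
    is the inter-cell background.  Raises when ``n_cells`` ellipses of the
    requested size cannot fit in the image.
    """
    h, wpix = params.image_shape
    w_um, h_um = wpix * params.pixel_size, h * params.pixel_size
    area = params.mean_area
    r_major = math.sqrt(area * params.aspect_ratio / math.pi)
    r_minor = math.sqrt(area / (params.aspect_ratio * math.pi))
    # lattice pitch: ellipses of any orientation must stay inside their site
    jitter = 0.05
    pitch = 2.0 * r_major * (1.0 + 2 * jitter) * 1.05
    nx = int(w_um // pitch)
    ny = int(h_um // pitch)
    if nx * ny < params.n_cells or params.n_cells * area > w_um * h_um:
        raise ValidationError(
            f"infeasible packing: {params.n_cells} cells of {area} um^2 "
            f"(major radius {r_major:.1f} um) do not fit in "
            f"{w_um:.0f} x {h_um:.0f} um")
    rng = np.random.default_rng(params.seed)
    sites = [(ix, iy) for iy in range(ny) for ix in range(nx)]
    order = rng.permutation(len(sites))[:params.n_cells]

    mask = np.zeros((h, wpix), dtype=np.uint16)
    rr, cc = np.mgrid[0:h, 0:wpix]
    px = (cc + 0.5) * params.pixel_size
    py = (rr + 0.5) * params.pixel_size
    for label, k in enumerate(order, start=1):
        ix, iy = sites[k]
        cx = (ix + 0.5) * pitch + rng.uniform(-jitter, jitter) * pitch
        cy = (iy + 0.5) * pitch + rng.uniform(-jitter, jitter) * pitch
        if params.orientation_kappa > 0:
            theta = rng.vonmises(0.0, params.orientation_kappa) / 2.0
        else:
            theta = rng.uniform(-math.pi / 2, math.pi / 2)
        ct, st = math.cos(theta), math.sin(theta)
        # rasterize within the ellipse's bounding box only
        r0 = max(int((cy - r_major) / params.pixel_size) - 1, 0)
        r1 = min(int((cy + r_major) / params.pixel_size) + 2, h)
        c0 = max(int((cx - r_major) / params.pixel_size) - 1, 0)
        c1 = min(int((cx + r_major) / params.pixel_size) + 2, wpix)
        dx = px[r0:r1, c0:c1] - cx
        dy = py[r0:r1, c0:c1] - cy
        uu = (dx * ct + dy * st) / r_major
        vv = (-dx * st + dy * ct) / r_minor
        inside = uu * uu + vv * vv <= 1.0
        sub = mask[r0:r1, c0:c1]
        sub[inside] = label
    return ImageLayer(mask, params.pixel_size, kind="label")


# ---------------------------------------------------------------------------
# Vegetal-view embryo annotations
# ---------------------------------------------------------------------------

def gen_embryo_vegetal_view(r_blastopore: float, r_vegetal: float,
                            center_offset: tuple[float, float] = (0.0, 0.0),
                            n_vertices: int = 64,
                            ) -> tuple[Optional[RegionAnnotation],
                                       RegionAnnotation]:
    """Concentric polygonal disks for blastopore and vegetal hemisphere.

    Both disks are centered at ``center_offset`` relative to the vegetal
    center. A fully closed blastopore (r = 0) is returned as ``None``
    (area 0), which ``closure_ratio`` maps to ratio 0.
    """
    if r_blastopore < 0 or r_vegetal <= 0:
        raise ValidationError("radii must be non-negative, vegetal positive")
    if r_blastopore > r_vegetal:
        raise ValidationError("blastopore radius exceeds vegetal radius")
    ang = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    ring = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    cx, cy = center_offset
    vegetal = RegionAnnotation(
        "vegetal_hemisphere", "polygon",
        r_vegetal * ring + np.array([cx, cy]))
    if r_blastopore == 0:
        return None, vegetal
    blastopore = RegionAnnotation(
        "blastopore", "polygon", r_blastopore * ring + np.array([cx, cy]))
    return blastopore, vegetal


# ---------------------------------------------------------------------------
# Fibril-band images
# ---------------------------------------------------------------------------

def gen_fibril_image(band_center: float, band_width: float,
                     band_amp: float = 1.0, background: float = 1.0,
                     noise_sd: float = 0.0,
                     image_shape: tuple[int, int] = (256, 256),
                     pixel_size: float = 1.0, seed: int = 0,
                     band_angle_deg: float = 0.0) -> ImageLayer:
    """Background plus a straight band of elevated intensity plus noise.

    The band centerline passes through (image width / 2, ``band_center``)
    um at ``band_angle_deg`` from the x-axis; pixels within half the band
    width of the centerline get ``background + band_amp``, the rest
    ``background``, then i.i.d. Gaussian noise of sd ``noise_sd`` is added.
    """
    h, w = image_shape
    w_um, h_um = w * pixel_size, h * pixel_size
    if not (0.0 <= band_center <= h_um):
        raise ValidationError("band_center outside the image")
    if band_width < 0 or noise_sd < 0:
        raise ValidationError("band_width and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:h, 0:w]
    x = (cc + 0.5) * pixel_size
    y = (rr + 0.5) * pixel_size
    a = math.radians(band_angle_deg)
    # signed distance to the centerline
    dist = np.abs(-(x - w_um / 2) * math.sin(a) + (y - band_center) * math.cos(a))
    img = np.full((h, w), float(background))
    img[dist <= band_width / 2.0] += band_amp
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return ImageLayer(img, pixel_size, kind="intensity")


def straight_lip(length: float = 400.0, y: float = 0.0,
                 n_vertices: int = 2) -> RegionAnnotation:
    """A straight horizontal lip polyline from (0, y) to (length, y)."""
    xs = np.linspace(0.0, length, max(n_vertices, 2))
    return RegionAnnotation("lip", "polyline",
                            np.stack([xs, np.full_like(xs, y)], axis=1))
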