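"""Cell-shape morphometrics from label masks.

Each labelled region is summarized by the ellipse with matched second
central moments: area, centroid, major/minor axis lengths (4 sqrt of the
covariance eigenvalues) and the major-axis orientation.  The polarity index
is major/minor (1 for an isotropic cell); orientation is folded to the
acute angle against the annotated mediolateral (ML) axis and binned over
[0, 90] degrees in 11.25-degree bins for the rose summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ImageLayer, ValidationError

__all__ = [
    "CellShape",
    "RoseSummary",
    "region_shapes",
    "orientation_to_ml",
    "polarity_index",
    "rose_summary",
]


@dataclass
class CellShape:
    label: int
    centroid: tuple[float, float]   # um
    area: float                     # um^2
    major_length: float             # um
    minor_length: float             # um
    orientation: float              # deg in (-90, 90], vs image x-axis
    touches_border: bool = False


def _moment_ellipse(rows: np.ndarray, cols: np.ndarray,
                    pixel_size: float) -> tuple[float, float, float]:
    """(major, minor, orientation_deg) of the moment-matched ellipse.

    Pixel coordinates are treated as unit squares: the covariance adds the
    1/12 variance of a uniform pixel so a single row of pixels still has a
    finite minor axis.  Orientation follows the package convention: degrees
    from the +x (column) axis, y downward, folded into (-90, 90].
    """
    x = (cols + 0.5) * pixel_size
    y = (rows + 0.5) * pixel_size
    xc, yc = x.mean(), y.mean()
    cxx = np.mean((x - xc) ** 2) + pixel_size ** 2 / 12.0
    cyy = np.mean((y - yc) ** 2) + pixel_size ** 2 / 12.0
    cxy = np.mean((x - xc) * (y - yc))
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = 4.0 * math.sqrt(max(evals[1], 0.0))
    minor = 4.0 * math.sqrt(max(evals[0], 0.0))
    vx, vy = evecs[:, 1]
    # undirected axis in the package's screen frame (x right, y down),
    # folded so the angle lies in (-90, 90] measured from +x; the ML axis
    # annotation must use the same frame
    ang = math.degrees(math.atan2(vy, vx))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return major, minor, ang


def region_shapes(mask: ImageLayer, min_pixels: int = 4,
                  exclude_border: bool = True) -> list[CellShape]:
    """Measure every labelled region of a mask.

    Regions touching the image border have incomplete shapes and are
    excluded by default (they are still flagged when kept). Regions smaller
    than ``min_pixels`` are dropped: their moments are meaningless.
    """
    if mask.kind != "label":
        raise ValidationError("region_shapes requires a label mask")
    px = mask.pixels
    h, w = px.shape
    shapes: list[CellShape] = []
    labels = np.unique(px)
    for lab in labels:
        if lab == 0:
            continue
        rows, cols = np.nonzero(px == lab)
        if rows.size < min_pixels:
            continue
        touches = bool(rows.min() == 0 or cols.min() == 0
                       or rows.max() == h - 1 or cols.max() == w - 1)
        if exclude_border and touches:
            continue
        major, minor, ang = _moment_ellipse(rows, cols, mask.pixel_size)
        area = rows.size * mask.pixel_size ** 2
        cx = float((cols.mean() + 0.5) * mask.pixel_size)
        cy = float((rows.mean() + 0.5) * mask.pixel_size)
        shapes.append(CellShape(
            label=int(lab), centroid=(cx, cy), area=float(area),
            major_length=float(major), minor_length=float(minor),
            orientation=float(ang), touches_border=touches))
    return shapes


def orientation_to_ml(orientation_deg: float,
                      ml_axis: Sequence[float]) -> float:
    """Acute angle between an undirected cell axis and the undirected ML
    axis, in [0, 90] degrees.

    ``ml_axis`` is a direction vector (or an angle via (cos, sin)); the sign
    of either axis direction is irrelevant.
    """
    mx, my = float(ml_axis[0]), float(ml_axis[1])
    norm = math.hypot(mx, my)
    if norm == 0.0:
        raise ValidationError("ML axis direction must be nonzero")
    ml_deg = math.degrees(math.atan2(my, mx))
    diff = abs(orientation_deg - ml_deg) % 180.0
    return min(diff, 180.0 - diff)


def polarity_index(shape: CellShape) -> float:
    """Major over minor axis length; 1 for an isotropic cell."""
    if shape.minor_length <= 0:
        raise ValidationError(f"region {shape.label}: degenerate (minor axis 0)")
    return shape.major_length / shape.minor_length


@dataclass
class RoseSummary:
    """Angular histogram over [0, 90] degrees."""

    bin_edges: np.ndarray   # (n_bins + 1,)
    counts: np.ndarray      # (n_bins,)

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.counts / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_deg": self.bin_edges[:-1],
            "bin_hi_deg": self.bin_edges[1:],
            "count": self.counts,
            "percent": self.percent,
        })


def rose_summary(angles: Sequence[float],
                 config: Optional[AnalysisConfig] = None) -> RoseSummary:
    """Bin ML angles into 11.25-degree bins over [0, 90].

    Bins are half-open, [0, 11.25), ..., except the last, [78.75, 90],
    closed so 90 degrees is binned exactly once.
    """
    config = config or AnalysisConfig()
    vals = np.asarray(list(angles), dtype=float)
    if vals.size == 0:
        raise ValidationError("rose_summary: empty input")
    if ((vals < 0) | (vals > 90)).any():
        raise ValidationError("angles must lie in [0, 90] degrees")
    n_bins = int(round(90.0 / config.rose_bin_width))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    idx = np.minimum((vals / config.rose_bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return RoseSummary(bin_edges=edges, counts=counts)


def shapes_to_frame(shapes: Sequence[CellShape],
                    ml_axis: Optional[Sequence[float]] = None) -> pd.DataFrame:
    rows = []
    for s in shapes:
        row = {
            "label": s.label,
            "centroid_x_um": s.centroid[0],
            "centroid_y_um": s.centroid[1],
            "area_um2": s.area,
            "major_um": s.major_length,
            "minor_um": s.minor_length,
            "orientation_deg": s.orientation,
            "polarity_index": polarity_index(s),
            "touches_border": s.touches_border,
        }
        if ml_axis is not None:
            row["ml_angle_deg"] = orientation_to_ml(s.orientation, ml_axis)
        rows.append(row)
    return pd.DataFrame(rows)
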