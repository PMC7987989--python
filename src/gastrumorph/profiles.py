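"""Normalized transverse intensity profiles across a rectangular ROI.

Fibrillar fibronectin along the cleft of Brachet is quantified inside a
25 x 100 um rectangle placed 300 um from the dorsal blastopore lip: the raw
intensity is averaged along the 100 um length at each transverse position x
across the 25 um width (I_x), normalized by the mean intensity of the whole
rectangle (I_m), and reported as the relative profile I_x / I_m.  The
per-rectangle normalization makes profiles comparable across embryos and
experiments through their shape, not their absolute brightness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .io import ImageLayer, RegionAnnotation, ValidationError

__all__ = [
    "ProfileRect",
    "NormalizedProfile",
    "sample_profile",
    "place_rect_from_lip",
]


@dataclass
class ProfileRect:
    """The sampling rectangle: 25 um across (transverse), 100 um long."""

    center: tuple[float, float]       # um
    direction: tuple[float, float]    # unit vector of the LONG axis
    width: float = 25.0               # um, transverse
    length: float = 100.0             # um, longitudinal
    anchor_distance: Optional[float] = None  # um from lip (metadata)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValidationError("rectangle width and length must be positive")
        dx, dy = self.direction
        norm = math.hypot(dx, dy)
        if norm == 0:
            raise ValidationError("rectangle direction must be nonzero")
        self.direction = (dx / norm, dy / norm)

    @property
    def transverse(self) -> tuple[float, float]:
        dx, dy = self.direction
        return (-dy, dx)

    def corners(self) -> np.ndarray:
        """4 corners in um, for export/review as an annotation."""
        c = np.asarray(self.center)
        u = np.asarray(self.direction) * self.length / 2
        v = np.asarray(self.transverse) * self.width / 2
        return np.array([c - u - v, c + u - v, c + u + v, c - u + v])


@dataclass
class NormalizedProfile:
    x: np.ndarray          # transverse positions in [0, width] um
    intensity: np.ndarray  # I_x: mean raw intensity along the length at x
    mean_intensity: float  # I_m: mean over the whole rectangle

    @property
    def relative(self) -> np.ndarray:
        """I_x / I_m; averages to 1 over the width by construction."""
        return self.intensity / self.mean_intensity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.x, "I_x": self.intensity,
                             "relative": self.relative})


def sample_profile(image: ImageLayer, rect: ProfileRect,
                   step: Optional[float] = None) -> NormalizedProfile:
    """Sample the rectangle on a regular grid and reduce to I_x / I_m.

    Bilinear interpolation on a grid with ``step`` um spacing along both
    axes (default: half the pixel size, Nyquist with respect to the
    raster).  The rectangle must lie fully inside the image.
    """
    if image.kind != "intensity":
        raise ValidationError("sample_profile requires an intensity image")
    if step is None:
        step = image.pixel_size / 2.0
    if step <= 0:
        raise ValidationError("step must be positive")
    w_um, h_um = image.extent_um
    corners = rect.corners()
    if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
            or corners[:, 0].max() > w_um or corners[:, 1].max() > h_um):
        raise ValidationError("profile rectangle exceeds image bounds")

    n_t = max(int(round(rect.width / step)) + 1, 2)
    n_l = max(int(round(rect.length / step)) + 1, 2)
    t = np.linspace(0.0, rect.width, n_t)       # transverse offset
    s = np.linspace(0.0, rect.length, n_l)      # longitudinal offset
    u = np.asarray(rect.direction)
    v = np.asarray(rect.transverse)
    origin = np.asarray(rect.center) - u * rect.length / 2 - v * rect.width / 2
    # grid of physical sample points (n_t, n_l, 2)
    pts = (origin[None, None, :]
           + s[None, :, None] * u[None, None, :]
           + t[:, None, None] * v[None, None, :])
    # um -> fractional pixel index; pixel centers at half-integers
    cols = pts[..., 0] / image.pixel_size - 0.5
    rows = pts[..., 1] / image.pixel_size - 0.5
    samples = map_coordinates(image.pixels.astype(float), [rows, cols],
                              order=1, mode="nearest")
    i_x = samples.mean(axis=1)
    i_m = float(samples.mean())
    if i_m <= 0:
        raise ValidationError("mean rectangle intensity is zero; cannot "
                              "normalize")
    return NormalizedProfile(x=t, intensity=i_x, mean_intensity=i_m)


def place_rect_from_lip(lip: RegionAnnotation, hint: Sequence[float],
                        anchor_distance: float = 300.0,
                        width: float = 25.0,
                        length: float = 100.0) -> ProfileRect:
    """Place the profile rectangle relative to the lip curve.

    The center sits ``anchor_distance`` um from the lip centroid along the
    user-supplied ``hint`` direction (pointing from the lip across the
    cleft); the rectangle's long axis runs perpendicular to the hint, i.e.
    parallel to the cleft, so the 25 um width crosses the fibronectin band.
    The placement is meant to be reviewed: export ``rect.corners()`` as an
    annotation.
    """
    if lip.kind != "polyline":
        raise ValidationError("lip must be a polyline")
    hx, hy = float(hint[0]), float(hint[1])
    norm = math.hypot(hx, hy)
    if norm == 0:
        raise ValidationError("direction hint must be nonzero")
    hx, hy = hx / norm, hy / norm
    centroid = lip.vertices.mean(axis=0)
    center = (centroid[0] + hx * anchor_distance,
              centroid[1] + hy * anchor_distance)
    return ProfileRect(center=center, direction=(-hy, hx),
                       width=width, length=length,
                       anchor_distance=anchor_distance)
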