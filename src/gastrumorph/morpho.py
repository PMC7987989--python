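"""Whole-embryo and explant morphometrics.

Blastopore closure is the ratio of the blastopore area over the area of the
vegetal hemisphere in vegetal view (0 = closed). Dorsal-midline elongation
is the length of a marker expression domain divided by whole-embryo length.
Explant elongation is the initial-to-final length change expressed as a
percentage of the mean length change of the uninjected reference group
(reference mean = 100%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import LineString, Polygon

from .io import ImageLayer, RegionAnnotation, ValidationError

__all__ = [
    "ClosureMeasurement",
    "ElongationMeasurement",
    "ExplantElongation",
    "polygon_area",
    "polyline_length",
    "closure_ratio",
    "elongation_ratio",
    "explant_percent_elongation",
]


@dataclass
class ClosureMeasurement:
    embryo_id: Optional[str]
    blastopore_area: float  # um^2
    vegetal_area: float     # um^2

    @property
    def ratio(self) -> float:
        return self.blastopore_area / self.vegetal_area


@dataclass
class ElongationMeasurement:
    embryo_id: Optional[str]
    domain_length: float  # um
    embryo_length: float  # um

    @property
    def ratio(self) -> float:
        return self.domain_length / self.embryo_length


@dataclass
class ExplantElongation:
    explant_id: object
    group: Optional[str]
    initial_length: float  # um
    final_length: float    # um
    percent: float         # relative to reference mean delta (=100%)

    @property
    def delta(self) -> float:
        return self.final_length - self.initial_length


def polygon_area(polygon: RegionAnnotation) -> float:
    """Absolute (orientation-independent) area of a simple polygon, um^2."""
    if polygon.kind != "polygon":
        raise ValidationError(f"{polygon.name!r} is not a polygon")
    poly = Polygon(polygon.vertices)
    if not poly.is_valid:
        raise ValidationError(f"polygon {polygon.name!r} is self-intersecting "
                              "or otherwise invalid")
    return float(poly.area)


def polyline_length(line: RegionAnnotation, chord: bool = False) -> float:
    """Arc length of a polyline in um; ``chord`` gives the straight
    first-to-last distance instead."""
    if len(line.vertices) < 2:
        raise ValidationError(f"{line.name!r}: need >= 2 vertices")
    if chord:
        return float(np.linalg.norm(line.vertices[-1] - line.vertices[0]))
    return float(LineString(line.vertices).length)


def _region_area(region: Union[RegionAnnotation, ImageLayer]) -> float:
    """Area of a polygon annotation or a binary/label mask, in um^2.

    A zero-area region may legitimately be a fully closed blastopore; it is
    represented as a degenerate annotation with area 0 via ``None``-like
    empty polygons upstream, so masks with no foreground return 0 here.
    """
    if isinstance(region, ImageLayer):
        return float(np.count_nonzero(region.pixels)) * region.pixel_size ** 2
    return polygon_area(region)


def closure_ratio(blastopore: Union[RegionAnnotation, ImageLayer, None],
                  vegetal: Union[RegionAnnotation, ImageLayer],
                  embryo_id: Optional[str] = None) -> ClosureMeasurement:
    """Blastopore area over vegetal-hemisphere area (0 = closed).

    ``blastopore=None`` denotes a fully closed blastopore (area 0). The
    ratio is not clamped: a value > 1 signals an annotation error and is
    reported with a warning. A blastopore annotation lying outside the
    vegetal region also warns rather than fails.
    """
    va = _region_area(vegetal)
    if va <= 0:
        raise ValidationError("vegetal hemisphere area must be positive")
    ba = 0.0 if blastopore is None else _region_area(blastopore)
    m = ClosureMeasurement(embryo_id, blastopore_area=ba, vegetal_area=va)
    if m.ratio > 1:
        warnings.warn(f"closure ratio {m.ratio:.3f} > 1: check annotations",
                      stacklevel=2)
    elif (isinstance(blastopore, RegionAnnotation)
          and isinstance(vegetal, RegionAnnotation)):
        bp = Polygon(blastopore.vertices)
        vp = Polygon(vegetal.vertices)
        if not vp.buffer(1e-6).contains(bp):
            warnings.warn("blastopore annotation extends outside the vegetal "
                          "hemisphere", stacklevel=2)
    return m


def elongation_ratio(domain_length: float, embryo_length: float,
                     embryo_id: Optional[str] = None) -> ElongationMeasurement:
    """Expression-domain length over whole-embryo length (both from
    annotated polylines, measured as arc length)."""
    if embryo_length <= 0:
        raise ValidationError("embryo length must be positive")
    if domain_length < 0:
        raise ValidationError("domain length must be non-negative")
    return ElongationMeasurement(embryo_id, domain_length, embryo_length)


def explant_percent_elongation(
        group: Sequence[tuple[float, float]],
        reference: Sequence[tuple[float, float]],
        group_label: Optional[str] = None) -> list[ExplantElongation]:
    """Percent elongation of explants relative to the uninjected reference.

    Each entry is (initial_length, final_length) in um.  The reference
    group's mean length change defines 100%; an explant that shrinks gets a
    negative percentage (not clamped).
    """
    if len(reference) == 0:
        raise ValidationError("reference group must be non-empty")
    ref_deltas = np.array([lf - li for li, lf in reference], dtype=float)
    ref_mean = float(ref_deltas.mean())
    if ref_mean <= 0:
        raise ValidationError(
            f"reference mean length change must be positive, got {ref_mean}")
    out = []
    for i, (li, lf) in enumerate(group):
        out.append(ExplantElongation(
            explant_id=i, group=group_label,
            initial_length=float(li), final_length=float(lf),
            percent=100.0 * (lf - li) / ref_mean))
    return out
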