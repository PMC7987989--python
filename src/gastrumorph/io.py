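"""Input/output, calibration and configuration for the morphogenesis pipeline.

All geometry throughout the package lives in a single convention: continuous
Cartesian micrometres, origin at the image top-left corner, x increasing to
the right (columns), y increasing downward (rows), and pixel centers at
half-integer pixel coordinates, i.e. the center of pixel ``(row, col)`` sits
at ``((col + 0.5) * pixel_size, (row + 0.5) * pixel_size)``.  Time is in
minutes.  Readers validate every structural invariant up front so the
analysis modules can assume clean inputs.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TrackTable",
    "ImageLayer",
    "RegionAnnotation",
    "AnalysisConfig",
    "ValidationError",
    "read_track_table",
    "write_track_table",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
]

TRACK_COLUMNS = ("cell_id", "frame", "t_min", "x_um", "y_um")
OPTIONAL_TRACK_COLUMNS = ("z_um", "group")


class ValidationError(ValueError):
    """An input file violated a structural invariant."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Every tunable parameter of the pipeline, with the published defaults.

    Lengths are micrometres, durations minutes, angles degrees.
    """

    frame_interval: float = 3.0          # min between consecutive frames
    min_duration: float = 45.0           # track filter (i): tracked >= 45 min
    min_displacement: float = 20.0       # track filter (ii): moved >= 20 um
    max_final_lip_distance: float = 80.0  # track filter (iii): end < 80 um from lip
    displacement_mode: str = "net"       # "net" (first-to-last) or "path"
    window_width: float = 30.0           # lip-distance window width
    window_step: float = 25.0            # consecutive windows overlap by 5 um
    rose_bin_width: float = 11.25        # orientation bins over [0, 90] deg
    profile_width: float = 25.0          # profile rectangle, transverse
    profile_length: float = 100.0        # profile rectangle, longitudinal
    profile_anchor_distance: float = 300.0  # rectangle center distance from lip
    analysis_frame_time: float = 150.0   # time point for spatial organization
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_interval", "min_duration", "min_displacement",
                     "max_final_lip_distance", "window_width", "window_step",
                     "rose_bin_width", "profile_width", "profile_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name!r} must be positive")
        if self.profile_anchor_distance < 0:
            raise ValidationError("profile_anchor_distance must be >= 0")
        n_bins = 90.0 / self.rose_bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValidationError(
                "rose_bin_width must divide 90 degrees evenly, got "
                f"{self.rose_bin_width}")
        if self.displacement_mode not in ("net", "path"):
            raise ValidationError("displacement_mode must be 'net' or 'path'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------

@dataclass
class TrackTable:
    """Long-format nuclear tracking data.

    ``data`` holds one row per (cell, frame) with columns
    ``cell_id, frame, t_min, x_um, y_um`` and optionally ``z_um`` and
    ``group``.  Rows are sorted by (cell_id, frame).
    """

    data: pd.DataFrame
    frame_interval: float = 3.0

    @property
    def has_z(self) -> bool:
        return "z_um" in self.data.columns

    @property
    def cell_ids(self) -> list:
        return list(self.data["cell_id"].unique())

    def positions(self, cell_id) -> np.ndarray:
        """(n, 2) or (n, 3) positions of one cell, time-ordered."""
        cols = ["x_um", "y_um"] + (["z_um"] if self.has_z else [])
        sub = self.data[self.data["cell_id"] == cell_id]
        return sub[cols].to_numpy(dtype=float)

    def validate(self) -> "TrackTable":
        df = self.data
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        coord_cols = ["t_min", "x_um", "y_um"] + (["z_um"] if self.has_z else [])
        bad = ~np.isfinite(df[coord_cols].to_numpy(dtype=float)).all(axis=1)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"non-finite coordinate at row {row} "
                                  f"(cell_id={df.iloc[row]['cell_id']})")
        if (df["frame"].to_numpy() < 0).any():
            raise ValidationError("negative frame index")
        dup = df.duplicated(subset=["cell_id", "frame"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate (cell_id, frame) pair: ({r['cell_id']}, {r['frame']})")
        for cid, sub in df.groupby("cell_id", sort=False):
            frames = sub["frame"].to_numpy()
            times = sub["t_min"].to_numpy(dtype=float)
            if not (np.diff(frames) > 0).all():
                raise ValidationError(f"frames not strictly increasing for cell {cid}")
            if not (np.diff(times) > 0).all():
                raise ValidationError(f"times not strictly increasing for cell {cid}")
            expected = np.diff(frames) * self.frame_interval
            if not np.allclose(np.diff(times), expected, rtol=1e-9, atol=1e-9):
                raise ValidationError(
                    f"time steps of cell {cid} inconsistent with "
                    f"frame_interval={self.frame_interval} min")
        return self

    def sorted(self) -> "TrackTable":
        df = self.data.sort_values(["cell_id", "frame"], kind="stable")
        return TrackTable(df.reset_index(drop=True), self.frame_interval)


def read_track_table(path: str | Path, config: Optional[AnalysisConfig] = None,
                     column_map: Optional[dict] = None) -> TrackTable:
    """Read a long-format tracking CSV and validate it.

    ``column_map`` maps the file's column names onto the canonical
    ``cell_id, frame, t_min, x_um, y_um[, z_um]`` names; trackers disagree on
    spellings, so the mapping is explicit rather than guessed.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {missing}; "
            "supply a column_map if the file uses different names")
    table = TrackTable(df, config.frame_interval).sorted()
    return table.validate()


def write_track_table(table: TrackTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclass
class ImageLayer:
    """A calibrated 2D grayscale raster, either intensities or integer labels."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel, isotropic
    kind: str = "intensity"  # "intensity" | "label"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("ImageLayer requires a 2D grid; "
                                  f"got shape {self.pixels.shape}")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.kind not in ("intensity", "label"):
            raise ValidationError(f"unknown image kind {self.kind!r}")
        if self.kind == "label":
            if not np.issubdtype(self.pixels.dtype, np.integer):
                raise ValidationError("label layers must have integer dtype")
            if (self.pixels < 0).any():
                raise ValidationError("label layers must be non-negative")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometres."""
        h, w = self.pixels.shape
        return w * self.pixel_size, h * self.pixel_size


def read_image(path: str | Path, pixel_size: float, kind: str = "intensity",
               page: Optional[int] = None) -> ImageLayer:
    """Read a grayscale TIFF with explicit calibration.

    Calibration is always user-supplied: microscope pixel sizes are not
    reliably stored in exported files. Multi-page files need an explicit
    ``page``; color images are rejected.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if n_pages > 1 and page is None:
            raise ValidationError(
                f"{path}: {n_pages} pages; an explicit page index is required")
        arr = tif.pages[page or 0].asarray()
    if arr.ndim == 3:
        raise ValidationError(f"{path}: grayscale required, got shape {arr.shape}")
    return ImageLayer(arr, pixel_size, kind)


def write_image(layer: ImageLayer, path: str | Path) -> None:
    tifffile.imwrite(path, layer.pixels)


# ---------------------------------------------------------------------------
# Region annotations
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """A named polygon or polyline in micrometres (lip curve, blastopore,
    vegetal hemisphere, mediolateral axis, profile rectangle outline...)."""

    name: str
    kind: str  # "polygon" | "polyline"
    vertices: np.ndarray  # (n, 2) um
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.kind not in ("polygon", "polyline"):
            raise ValidationError(f"annotation {self.name!r}: unknown geometry "
                                  f"kind {self.kind!r}")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError(f"annotation {self.name!r}: vertices must be "
                                  "an (n, 2) array")
        if not np.isfinite(self.vertices).all():
            raise ValidationError(f"annotation {self.name!r}: non-finite vertex")
        if self.kind == "polyline" and len(self.vertices) < 2:
            raise ValidationError(f"annotation {self.name!r}: polyline needs "
                                  ">= 2 vertices")
        if self.kind == "polygon":
            if len(self.vertices) < 3:
                raise ValidationError(f"annotation {self.name!r}: polygon needs "
                                      ">= 3 vertices")
            x, y = self.vertices[:, 0], self.vertices[:, 1]
            area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
            if abs(area2) < 1e-300:
                raise ValidationError(f"annotation {self.name!r}: zero-area polygon")


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read a list of annotations from structured JSON (units: um)."""
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = [raw]
    out = []
    for entry in raw:
        out.append(RegionAnnotation(
            name=entry["name"],
            kind=entry["type"],
            vertices=np.asarray(entry["vertices_um"], dtype=float),
            frame=entry.get("frame"),
        ))
    return out


def write_annotations(annotations: Sequence[RegionAnnotation],
                      path: str | Path) -> None:
    payload = [
        {
            "name": a.name,
            "type": a.kind,
            "vertices_um": a.vertices.tolist(),
            "frame": a.frame,
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def find_annotation(annotations: Sequence[RegionAnnotation],
                    name: str) -> RegionAnnotation:
    for a in annotations:
        if a.name == name:
            return a
    raise KeyError(f"no annotation named {name!r}")
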