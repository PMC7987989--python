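"""Motility metrics for nuclear tracks.

A cell's instantaneous velocity is its spatial displacement over two
consecutive frames divided by the elapsed time, ``v = |dr| / dt``.
Directional persistence is the ratio between the linear (start-to-end)
distance a cell travels and the total length of its migration path: a cell
moving in a straight line has persistence 1, an erratic cell less.

Tracks feeding group comparisons are filtered by three criteria:
(i) tracked for at least 45 min, (ii) moved at least 20 um, and
(iii) ended closer than 80 um to the dorsal blastopore lip.  Metrics run in
3D when a z column is present, otherwise in 2D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AnalysisConfig, RegionAnnotation, TrackTable, ValidationError
from .spatial import distance_to_lip

__all__ = [
    "Trajectory",
    "TrackSummary",
    "instantaneous_speeds",
    "track_geometry",
    "track_persistence",
    "mean_track_speed",
    "filter_tracks",
    "summarize_track",
    "persistence_histogram",
    "PERSISTENCE_BIN_EDGES",
]


@dataclass
class Trajectory:
    """One cell's time-ordered samples: times (min), positions (um)."""

    cell_id: object
    times: np.ndarray        # (n,) minutes, strictly increasing
    positions: np.ndarray    # (n, 2) or (n, 3) um
    frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValidationError("positions must be (n, 2) or (n, 3)")
        if len(self.times) != len(self.positions):
            raise ValidationError("times and positions length mismatch")
        if len(self.times) >= 2 and not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_table(cls, table: TrackTable, cell_id) -> "Trajectory":
        sub = table.data[table.data["cell_id"] == cell_id]
        if sub.empty:
            raise KeyError(f"no rows for cell {cell_id!r}")
        cols = ["x_um", "y_um"] + (["z_um"] if table.has_z else [])
        return cls(cell_id,
                   sub["t_min"].to_numpy(dtype=float),
                   sub[cols].to_numpy(dtype=float),
                   sub["frame"].to_numpy())


@dataclass
class TrackSummary:
    """Per-cell motility scalars plus the three filter flags."""

    cell_id: object
    n_samples: int
    duration: float            # min
    net_displacement: float    # um
    path_length: float         # um
    persistence: Optional[float]  # None when the cell never moved
    mean_speed: float          # um/min
    final_lip_distance: Optional[float] = None
    passed_duration: bool = False
    passed_displacement: bool = False
    passed_lip_distance: bool = False
    group: Optional[str] = None

    @property
    def passed_filters(self) -> bool:
        return (self.passed_duration and self.passed_displacement
                and self.passed_lip_distance)


def _require_samples(traj: Trajectory, n: int = 2) -> None:
    if len(traj) < n:
        raise ValidationError(
            f"cell {traj.cell_id!r}: metric needs >= {n} samples, has {len(traj)}")


def instantaneous_speeds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per consecutive sample pair: (midpoint time, speed in um/min).

    Frame gaps are allowed; the true time difference is used.
    """
    _require_samples(traj)
    dt = np.diff(traj.times)
    if (dt <= 0).any():
        raise ValidationError("non-positive time step")
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    t_mid = 0.5 * (traj.times[:-1] + traj.times[1:])
    return t_mid, steps / dt


def track_geometry(traj: Trajectory) -> tuple[float, float, float]:
    """(net_displacement um, path_length um, duration min)."""
    _require_samples(traj)
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    path = float(np.linalg.norm(np.diff(traj.positions, axis=0), axis=1).sum())
    duration = float(traj.times[-1] - traj.times[0])
    return net, path, duration


def track_persistence(traj: Trajectory) -> float:
    """Net displacement over path length, in [0, 1].

    Raises for a perfectly stationary track (path length 0), where the ratio
    is undefined; callers exclude such cells from summaries.
    """
    net, path, _ = track_geometry(traj)
    if path == 0.0:
        raise ValidationError(
            f"cell {traj.cell_id!r}: stationary track, persistence undefined")
    return net / path


def mean_track_speed(traj: Trajectory, reducer: str = "mean") -> float:
    """Per-cell scalar velocity: mean (default) or median of the
    instantaneous speeds."""
    _, speeds = instantaneous_speeds(traj)
    if reducer == "mean":
        return float(speeds.mean())
    if reducer == "median":
        return float(np.median(speeds))
    raise ValueError(f"unknown reducer {reducer!r}")


def summarize_track(traj: Trajectory, lip: Optional[RegionAnnotation],
                    config: AnalysisConfig) -> TrackSummary:
    net, path, duration = track_geometry(traj)
    persistence = net / path if path > 0 else None
    speed = mean_track_speed(traj)
    lipdist = None
    if lip is not None:
        lipdist = distance_to_lip(traj.positions[-1][:2], lip)
    displacement = net if config.displacement_mode == "net" else path
    return TrackSummary(
        cell_id=traj.cell_id,
        n_samples=len(traj),
        duration=duration,
        net_displacement=net,
        path_length=path,
        persistence=persistence,
        mean_speed=speed,
        final_lip_distance=lipdist,
        passed_duration=duration >= config.min_duration,
        passed_displacement=displacement >= config.min_displacement,
        passed_lip_distance=(lipdist is not None
                             and lipdist < config.max_final_lip_distance),
    )


def filter_tracks(table: TrackTable, lip: Optional[RegionAnnotation],
                  config: Optional[AnalysisConfig] = None,
                  require_lip: bool = True,
                  ) -> tuple[TrackTable, list[TrackSummary]]:
    """Apply the three selection criteria to every cell of a track table.

    Returns the table restricted to passing cells plus a summary (with
    per-criterion flags) for every cell.  Criteria (i) and (ii) are
    inclusive ("at least"); criterion (iii) is strict ("closer than").
    When ``require_lip`` is False, criterion (iii) is skipped and every cell
    passes it vacuously.
    """
    config = config or AnalysisConfig()
    if lip is None and require_lip:
        raise ValidationError("lip curve required for the final-distance "
                              "criterion; pass require_lip=False to disable")
    groups = None
    if "group" in table.data.columns:
        groups = table.data.groupby("cell_id", sort=False)["group"].first()
    summaries = []
    kept_ids = []
    for cid in table.cell_ids:
        traj = Trajectory.from_table(table, cid)
        if len(traj) < 2:
            continue
        s = summarize_track(traj, lip, config)
        if lip is None:
            s.passed_lip_distance = True
        if groups is not None:
            s.group = groups[cid]
        summaries.append(s)
        if s.passed_filters:
            kept_ids.append(cid)
    kept = table.data[table.data["cell_id"].isin(kept_ids)]
    return TrackTable(kept.reset_index(drop=True), table.frame_interval), summaries


# Persistence histogram: 0.05-wide bins descending from 1.0 down to 0.70,
# plus one aggregate bin below 0.70.
PERSISTENCE_BIN_EDGES = (0.95, 0.90, 0.85, 0.80, 0.75, 0.70)


def persistence_histogram(values: Sequence[float]) -> pd.DataFrame:
    """Bin persistence values into the published intervals.

    Bins, in order: [0.95, 1.00], [0.90, 0.95), ..., [0.70, 0.75), [0, 0.70).
    Returns a DataFrame with columns bin_lo, bin_hi, count, percent;
    percentages sum to 100.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("persistence_histogram: empty input")
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("persistence values must lie in [0, 1]")
    rows = []
    prev_hi = 1.0
    for lo in PERSISTENCE_BIN_EDGES:
        if prev_hi == 1.0:
            count = int(((vals >= lo) & (vals <= prev_hi)).sum())
        else:
            count = int(((vals >= lo) & (vals < prev_hi)).sum())
        rows.append((lo, prev_hi, count))
        prev_hi = lo
    rows.append((0.0, 0.70, int((vals < 0.70).sum())))
    df = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "count"])
    df["percent"] = 100.0 * df["count"] / len(vals)
    return df


def summaries_to_frame(summaries: Sequence[TrackSummary]) -> pd.DataFrame:
    """Flatten TrackSummary records into a DataFrame (one row per cell)."""
    rows = []
    for s in summaries:
        rows.append({
            "cell_id": s.cell_id,
            "group": s.group,
            "n_samples": s.n_samples,
            "duration_min": s.duration,
            "net_displacement_um": s.net_displacement,
            "path_length_um": s.path_length,
            "persistence": s.persistence,
            "mean_speed_um_per_min": s.mean_speed,
            "final_lip_distance_um": s.final_lip_distance,
            "passed_duration": s.passed_duration,
            "passed_displacement": s.passed_displacement,
            "passed_lip_distance": s.passed_lip_distance,
            "passed_filters": s.passed_filters,
        })
    return pd.DataFrame(rows)
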