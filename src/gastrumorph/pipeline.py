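"""End-to-end orchestration: simulate or load, measure, stratify, test.

``run_track_pipeline`` reproduces the motility analysis (per-cell
summaries, persistence histogram, windowed neighbor statistics and the
group tests); ``run_shape_pipeline`` reproduces the cell-shape analysis
(per-cell morphometrics, rose summary and group tests).
``direction_of_effect`` runs both on the package's default synthetic
conditions and reports the sign of every group difference.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import synthetic
from .io import (AnalysisConfig, ImageLayer, RegionAnnotation, TrackTable,
                 ValidationError)
from .shapes import (region_shapes, rose_summary, shapes_to_frame)
from .spatial import (cloud_from_table, delaunay_graph, distances_to_lip,
                      mean_neighbor_distance, windowed_neighbor_stats,
                      windows_to_frame)
from .stats import (chi_square_table, dunn_posthoc, kruskal_wallis,
                    mann_whitney_u)
from .tracks import (filter_tracks, persistence_histogram, summaries_to_frame)

__all__ = [
    "RunManifest",
    "TrackPipelineResult",
    "ShapePipelineResult",
    "run_track_pipeline",
    "run_shape_pipeline",
    "direction_of_effect",
]


@dataclass
class RunManifest:
    """What went into a run: config, seed, input digests, outputs."""

    config: AnalysisConfig
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": {k: v for k, v in vars(self.config).items()},
            "input_digests": self.input_digests,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class TrackPipelineResult:
    summaries: pd.DataFrame          # one row per tracked cell
    histograms: dict[str, pd.DataFrame]   # persistence histogram per group
    windows: dict[str, pd.DataFrame]      # windowed NN stats per group
    tests: dict[str, object]
    filter_log: dict[str, dict[str, int]]  # per group: cells in/kept per criterion


@dataclass
class ShapePipelineResult:
    shapes: dict[str, pd.DataFrame]
    roses: dict[str, pd.DataFrame]
    tests: dict[str, object]


def run_track_pipeline(table: TrackTable, lip: RegionAnnotation,
                       config: Optional[AnalysisConfig] = None,
                       ) -> TrackPipelineResult:
    """Filter tracks, compute motility metrics and windowed neighbor
    distances per group, and run the published group comparisons.

    Requires a ``group`` column with two or more labels; every group must
    retain at least one cell after filtering.
    """
    config = config or AnalysisConfig()
    if "group" not in table.data.columns:
        raise ValidationError("track table needs a 'group' column")
    groups = list(dict.fromkeys(table.data["group"]))
    if len(groups) < 2:
        raise ValidationError("need >= 2 labeled groups")
    kept, summaries = filter_tracks(table, lip, config)
    sdf = summaries_to_frame(summaries)
    filter_log = {}
    for g in groups:
        gdf = sdf[sdf["group"] == g]
        filter_log[g] = {
            "cells_in": int(len(gdf)),
            "passed_duration": int(gdf["passed_duration"].sum()),
            "passed_displacement": int(gdf["passed_displacement"].sum()),
            "passed_lip_distance": int(gdf["passed_lip_distance"].sum()),
            "kept": int(gdf["passed_filters"].sum()),
        }
        if filter_log[g]["kept"] == 0:
            raise ValidationError(f"group {g!r}: no cells pass the track filters")

    passed = sdf[sdf["passed_filters"]]
    per_group_pers = {g: passed[passed["group"] == g]["persistence"].dropna()
                      for g in groups}
    per_group_speed = {g: passed[passed["group"] == g]["mean_speed_um_per_min"]
                       for g in groups}

    histograms = {g: persistence_histogram(v) for g, v in per_group_pers.items()}
    windows = {}
    window_values: dict[str, list] = {}
    for g in groups:
        gtable = TrackTable(
            kept.data[kept.data["group"] == g].reset_index(drop=True),
            kept.frame_interval)
        cloud = cloud_from_table(gtable, config.analysis_frame_time)
        if len(cloud.points) < 3:
            # too few nuclei tracked at this frame (e.g. already involuted)
            windows[g] = windows_to_frame([])
            window_values[g] = []
            continue
        graph = delaunay_graph(cloud)
        nn = mean_neighbor_distance(cloud, graph, exclude_hull=True)
        lipd = distances_to_lip(cloud.points, lip)
        stats = windowed_neighbor_stats(nn, lipd, config)
        windows[g] = windows_to_frame(stats)
        finite = np.isfinite(nn)
        window_values[g] = [nn[finite & (lipd >= w.d_lo) & (lipd < w.d_hi)]
                            for w in stats]

    tests: dict[str, object] = {}
    g0, g1 = groups[0], groups[1]
    tests["persistence_mwu"] = mann_whitney_u(per_group_pers[g0],
                                              per_group_pers[g1],
                                              names=(g0, g1))
    tests["speed_mwu"] = mann_whitney_u(per_group_speed[g0],
                                        per_group_speed[g1], names=(g0, g1))
    counts = np.array([histograms[g0]["count"], histograms[g1]["count"]])
    nonzero = counts.sum(axis=0) > 0
    tests["histogram_chi2"] = chi_square_table(counts[:, nonzero])
    # Kruskal-Wallis + Dunn across groups on near-lip window values
    near = [vals[0] for vals in window_values.values()
            if len(vals) and len(vals[0]) > 0]
    if len(near) >= 2:
        tests["near_lip_kw"] = kruskal_wallis(near, names=groups[:len(near)])
        tests["near_lip_dunn"] = dunn_posthoc(near, names=groups[:len(near)])
    return TrackPipelineResult(summaries=sdf, histograms=histograms,
                               windows=windows, tests=tests,
                               filter_log=filter_log)


def run_shape_pipeline(masks: dict[str, ImageLayer],
                       ml_axis: tuple[float, float],
                       config: Optional[AnalysisConfig] = None,
                       min_cells: int = 10) -> ShapePipelineResult:
    """Morphometrics per mask (group), rose summaries and group tests."""
    config = config or AnalysisConfig()
    shapes_frames = {}
    roses = {}
    for g, mask in masks.items():
        shp = region_shapes(mask)
        if len(shp) < min_cells:
            raise ValidationError(
                f"mask {g!r}: only {len(shp)} interior cells (< {min_cells})")
        df = shapes_to_frame(shp, ml_axis=ml_axis)
        shapes_frames[g] = df
        roses[g] = rose_summary(df["ml_angle_deg"], config).to_frame()
    tests: dict[str, object] = {}
    groups = list(masks)
    if len(groups) >= 2:
        g0, g1 = groups[0], groups[1]
        tests["polarity_mwu"] = mann_whitney_u(
            shapes_frames[g0]["polarity_index"],
            shapes_frames[g1]["polarity_index"], names=(g0, g1))
        tests["area_mwu"] = mann_whitney_u(
            shapes_frames[g0]["area_um2"], shapes_frames[g1]["area_um2"],
            names=(g0, g1))
        counts = np.array([roses[g0]["count"], roses[g1]["count"]])
        nonzero = counts.sum(axis=0) > 0
        tests["rose_chi2"] = chi_square_table(counts[:, nonzero])
    return ShapePipelineResult(shapes=shapes_frames, roses=roses, tests=tests)


def _morphant_spacing(d: float) -> float:
    """Near-lip nuclear crowding of the morphant-like condition: 7 um
    spacing within 40 um of the lip, relaxing to the control 10 um by 70 um."""
    if d < 40.0:
        return 7.0
    if d < 70.0:
        return 7.0 + 3.0 * (d - 40.0) / 30.0
    return 10.0


def direction_of_effect(seed: int = 0, n_cells: int = 60,
                        config: Optional[AnalysisConfig] = None) -> dict:
    """Run the default synthetic conditions end to end and report the sign
    of every group difference the metrics are designed to detect.

    Returns a dict with per-readout control/morphant values and booleans
    stating whether the morphant-like group is lower (persistence,
    velocity, near-lip neighbor distance, polarity index, ML orientation
    concentration).
    """
    if config is None:
        # nuclei of both synthetic groups are still tracked at 30 min;
        # control-like cells involute (and leave the table) well before the
        # 150 min default
        config = AnalysisConfig(analysis_frame_time=30.0)
    lip = synthetic.straight_lip(length=400.0)

    table = synthetic.gen_track_dataset(n_cells, lip, seed=seed)
    bundle = run_track_pipeline(table, lip, config)
    passed = bundle.summaries[bundle.summaries["passed_filters"]]
    pers = passed.groupby("group")["persistence"].mean()
    speed = passed.groupby("group")["mean_speed_um_per_min"].mean()

    clouds = {
        "control": synthetic.gen_point_cloud(
            synthetic.CloudParams(spacing=lambda d: 10.0, seed=seed,
                                  jitter_sd=0.5), lip),
        "morphant": synthetic.gen_point_cloud(
            synthetic.CloudParams(spacing=_morphant_spacing, seed=seed + 1,
                                  jitter_sd=0.5), lip),
    }
    near_nn = {}
    for g, cloud in clouds.items():
        graph = delaunay_graph(cloud)
        nn = mean_neighbor_distance(cloud, graph, exclude_hull=True)
        lipd = distances_to_lip(cloud.points, lip)
        w = windowed_neighbor_stats(nn, lipd, config)[0]  # [0, 30) um
        near_nn[g] = w.mean

    masks = {
        "control": synthetic.gen_cell_mosaic(synthetic.MosaicParams(
            aspect_ratio=1.9, orientation_kappa=8.0, seed=seed)),
        "morphant": synthetic.gen_cell_mosaic(synthetic.MosaicParams(
            aspect_ratio=1.6, orientation_kappa=1.5, seed=seed + 1)),
    }
    shapes = run_shape_pipeline(masks, ml_axis=(1.0, 0.0), config=config)
    polarity = {g: float(df["polarity_index"].mean())
                for g, df in shapes.shapes.items()}
    bin1 = {g: float(r["percent"].iloc[0]) for g, r in shapes.roses.items()}

    return {
        "persistence": {"control": float(pers["control"]),
                        "morphant": float(pers["morphant"]),
                        "morphant_lower": bool(pers["morphant"] < pers["control"])},
        "velocity": {"control": float(speed["control"]),
                     "morphant": float(speed["morphant"]),
                     "morphant_lower": bool(speed["morphant"] < speed["control"])},
        "near_lip_nn_distance": {"control": near_nn["control"],
                                 "morphant": near_nn["morphant"],
                                 "morphant_lower": bool(
                                     near_nn["morphant"] < near_nn["control"])},
        "polarity_index": {"control": polarity["control"],
                           "morphant": polarity["morphant"],
                           "morphant_lower": bool(
                               polarity["morphant"] < polarity["control"])},
        "ml_alignment_bin1_percent": {"control": bin1["control"],
                                      "morphant": bin1["morphant"],
                                      "morphant_lower": bool(
                                          bin1["morphant"] < bin1["control"])},
        "tests": bundle.tests,
    }
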