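"""Motility metrics: velocity, persistence, filters, histogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastrumorph import (AnalysisConfig, TrackTable, ValidationError,
                         filter_tracks, instantaneous_speeds,
                         mean_track_speed, persistence_histogram,
                         track_geometry, track_persistence)
from gastrumorph.tracks import Trajectory


def traj(points, dt=3.0):
    pts = np.asarray(points, dtype=float)
    return Trajectory("c", dt * np.arange(len(pts)), pts)


L_PATH = traj([(0, 0), (3, 0), (3, 4)])  # net 5, path 7


class TestInstantaneousSpeeds:
    @pytest.mark.parametrize("points,expected", [
        ([(0, 0), (6, 0)], [2.0]),
        ([(1, 1), (1, 1)], [0.0]),
        ([(0, 0), (3, 4)], [5.0 / 3.0]),
    ])
    def test_hand_values(self, points, expected):
        _, speeds = instantaneous_speeds(traj(points))
        np.testing.assert_allclose(speeds, expected, rtol=1e-12)

    def test_frame_gap_uses_true_time(self):
        t = Trajectory("c", [0.0, 3.0, 12.0], [(0, 0), (3, 0), (12, 0)])
        _, speeds = instantaneous_speeds(t)
        np.testing.assert_allclose(speeds, [1.0, 1.0])

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            instantaneous_speeds(Trajectory("c", [0.0], [(0, 0)]))


class TestGeometryAndPersistence:
    def test_l_path_hand_arithmetic(self):
        net, path, duration = track_geometry(L_PATH)
        assert (net, path, duration) == (5.0, 7.0, 6.0)
        assert track_persistence(L_PATH) == pytest.approx(5.0 / 7.0)

    def test_out_and_back_zero_persistence(self):
        t = traj([(0, 0), (1, 0), (0, 0)])
        net, path, _ = track_geometry(t)
        assert (net, path) == (0.0, 2.0)
        assert track_persistence(t) == 0.0

    def test_straight_line_persistence_is_one(self):
        t = traj([(2 * i, 0) for i in range(16)])
        assert track_persistence(t) == 1.0

    def test_single_segment_net_equals_path(self):
        t = traj([(1, 2), (4, 6)])
        net, path, _ = track_geometry(t)
        assert net == path

    def test_stationary_track_flagged_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            track_persistence(traj([(1, 1), (1, 1)]))

    def test_3d_track(self):
        t = traj([(0, 0, 0), (1, 2, 2)])
        net, path, _ = track_geometry(t)
        assert net == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=8),
           st.floats(-180, 180), st.floats(-50, 50), st.floats(-50, 50))
    def test_persistence_invariant_under_rigid_motion(self, pts, ang, dx, dy):
        pts = np.asarray(pts)
        base = traj(pts)
        net, path, _ = track_geometry(base)
        if path <= 1e-9:
            return
        a = np.radians(ang)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        moved = traj(pts @ rot.T + [dx, dy])
        assert track_persistence(moved) == pytest.approx(
            track_persistence(base), abs=1e-9)
        # speeds are rigid-invariant too; uniform scaling scales them
        _, s0 = instantaneous_speeds(base)
        _, s1 = instantaneous_speeds(moved)
        np.testing.assert_allclose(s0, s1, atol=1e-9)
        _, s2 = instantaneous_speeds(traj(pts * 2.5))
        np.testing.assert_allclose(s2, 2.5 * s0, atol=1e-9)

    def test_geometry_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.uniform(-50, 50, size=(5, 2))
            net, path, _ = track_geometry(traj(pts))
            brute_path = sum(
                float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(4))
            brute_net = float(np.hypot(*(pts[-1] - pts[0])))
            assert net == pytest.approx(brute_net, rel=1e-12)
            assert path == pytest.approx(brute_path, rel=1e-12)


class TestMeanSpeed:
    def test_constant_speed(self):
        t = traj([(0, 0), (6, 0), (12, 0)])
        assert mean_track_speed(t) == 2.0

    def test_l_path_mean(self):
        assert mean_track_speed(L_PATH) == pytest.approx(7.0 / 6.0)

    def test_median_option(self):
        t = traj([(0, 0), (3, 0), (12, 0)])  # speeds 1, 3
        assert mean_track_speed(t) == 2.0
        assert mean_track_speed(t, reducer="median") == 2.0


def _one_cell_df(cid, positions, dt=3.0, t0=0.0, f0=0):
    pts = np.asarray(positions, dtype=float)
    return pd.DataFrame({
        "cell_id": cid, "frame": f0 + np.arange(len(pts)),
        "t_min": t0 + dt * np.arange(len(pts)),
        "x_um": pts[:, 0], "y_um": pts[:, 1]})


class TestFilterTracks:
    """Criteria: >= 45 min, >= 20 um, final distance < 80 um (strict)."""

    def _table(self, frames):
        return TrackTable(pd.concat(frames, ignore_index=True)).validate()

    def test_boundary_passing_track_kept(self, lip):
        # 45 min (16 samples), net 25 um, ends 50 um above the lip
        pts = [(200.0, 75.0 - 25.0 * i / 15.0) for i in range(16)]
        table = self._table([_one_cell_df("ok", pts)])
        kept, summaries = filter_tracks(table, lip)
        assert kept.cell_ids == ["ok"]
        s = summaries[0]
        assert s.duration == 45.0
        assert s.passed_duration and s.passed_displacement
        assert s.passed_lip_distance

    def test_short_track_flagged(self, lip):
        pts = [(200.0, 70.0 - 4.0 * i) for i in range(15)]  # 42 min
        table = self._table([_one_cell_df("short", pts)])
        kept, summaries = filter_tracks(table, lip)
        assert kept.cell_ids == []
        assert not summaries[0].passed_duration
        assert summaries[0].passed_displacement

    def test_final_distance_exactly_80_excluded(self, lip):
        pts = [(200.0, 120.0 - 40.0 * i / 15.0) for i in range(16)]
        table = self._table([_one_cell_df("edge", pts)])
        _, summaries = filter_tracks(table, lip)
        assert summaries[0].final_lip_distance == pytest.approx(80.0)
        assert not summaries[0].passed_lip_distance

    def test_missing_lip_rejected_unless_disabled(self):
        pts = [(0.0, 50.0 - 2.0 * i) for i in range(16)]
        table = self._table([_one_cell_df("a", pts)])
        with pytest.raises(ValidationError, match="lip"):
            filter_tracks(table, None)
        kept, _ = filter_tracks(table, None, require_lip=False)
        assert kept.cell_ids == ["a"]

    def test_path_displacement_mode(self, lip):
        # jittery track: path 30 um but net 2 um
        pts = [(200.0, 50.0 + (i % 2) * 1.0) for i in range(31)]
        table = self._table([_one_cell_df("jig", pts)])
        _, s_net = filter_tracks(table, lip)
        assert not s_net[0].passed_displacement
        cfg = AnalysisConfig(displacement_mode="path")
        _, s_path = filter_tracks(table, lip, cfg)
        assert s_path[0].passed_displacement


class TestPersistenceHistogram:
    def test_top_bin_only(self):
        df = persistence_histogram([1.0, 0.96])
        assert df["percent"].iloc[0] == 100.0

    def test_hand_counted_distribution(self):
        df = persistence_histogram([0.96, 0.72, 0.60, 0.50])
        assert df["percent"].iloc[0] == 25.0        # [0.95, 1.00]
        assert df["percent"].iloc[5] == 25.0        # [0.70, 0.75)
        assert df["percent"].iloc[6] == 50.0        # [0, 0.70)
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            persistence_histogram([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            persistence_histogram([1.2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_percentages_sum_to_100_and_counts_partition(self, vals):
        df = persistence_histogram(vals)
        assert df["count"].sum() == len(vals)
        assert df["percent"].sum() == pytest.approx(100.0)
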