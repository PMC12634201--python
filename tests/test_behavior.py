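import numpy as np
import pandas as pd
import pytest

from gliamorph import synth
from gliamorph.behavior import (
    EmptyTrajectoryError,
    Trajectory,
    body_segment_angle,
    gait_amplitude,
    grip_index,
    locomotion_metrics,
    occupancy_map,
    straight_walk_segments,
)


def make_traj(xy_cm: np.ndarray, fps: float = 30.0, cm_per_px: float = 0.1,
              likelihood: np.ndarray | None = None) -> Trajectory:
    """Trajectory with all keypoints stacked on one path (tests of hip metrics)."""
    n = len(xy_cm)
    lk = np.ones(n) if likelihood is None else likelihood
    cols = {"t": np.arange(n) / fps}
    for kp in ("nose", "hip", "tail_base", "centroid"):
        cols[f"{kp}_x"] = xy_cm[:, 0] / cm_per_px
        cols[f"{kp}_y"] = xy_cm[:, 1] / cm_per_px
        cols[f"{kp}_likelihood"] = lk
    return Trajectory(data=pd.DataFrame(cols), fps=fps, cm_per_px=cm_per_px)


class TestLocomotion:
    def test_constant_speed_straight_walk(self):
        spec = synth.WalkSpec(
            duration_s=10, fps=30, speed_cm_s=5, turn_sd_deg=0,
            gait_amplitude_deg=0, dropout_rate=0.0, seed=1,
        )
        m = locomotion_metrics(synth.make_trajectory(spec))
        assert m["total_distance_cm"] == pytest.approx(50.0, rel=0.01)
        assert m["average_speed_cm_s"] == pytest.approx(5.0, abs=0.05)
        assert m["max_speed_cm_s"] == pytest.approx(5.0, abs=0.1)

    def test_stationary_trajectory_zero_distance(self):
        xy = np.tile([10.0, 10.0], (60, 1))
        m = locomotion_metrics(make_traj(xy))
        assert m["total_distance_cm"] == 0.0

    def test_square_perimeter_path_length(self):
        side = 10.0
        pts = []
        for leg in range(4):
            for i in range(50):
                f = i / 50
                if leg == 0:
                    pts.append((side * f, 0))
                elif leg == 1:
                    pts.append((side, side * f))
                elif leg == 2:
                    pts.append((side * (1 - f), side))
                else:
                    pts.append((0, side * (1 - f)))
        pts.append((0.0, 0.0))
        m = locomotion_metrics(make_traj(np.array(pts)))
        assert m["total_distance_cm"] == pytest.approx(40.0, rel=0.01)

    def test_distance_invariant_to_rigid_motion_and_linear_in_calibration(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 0.3, size=(100, 2)), axis=0) + 20
        base = locomotion_metrics(make_traj(xy))["total_distance_cm"]
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ R.T + [5.0, -3.0]
        assert locomotion_metrics(make_traj(moved))["total_distance_cm"] == pytest.approx(
            base, rel=1e-9
        )
        doubled = make_traj(xy, cm_per_px=0.2)  # same pixels, doubled calibration
        doubled_xy = make_traj(xy * 2.0, cm_per_px=0.2)
        assert locomotion_metrics(doubled_xy)["total_distance_cm"] == pytest.approx(
            2 * base, rel=1e-9
        )

    def test_low_confidence_frames_interpolated(self):
        xy = np.column_stack([np.linspace(0, 10, 101), np.zeros(101)])
        lk = np.ones(101)
        lk[40:43] = 0.1  # 3-frame dropout on a straight path
        m = locomotion_metrics(make_traj(xy, likelihood=lk))
        assert m["total_distance_cm"] == pytest.approx(10.0, rel=0.01)

    def test_all_frames_below_confidence_raise(self):
        xy = np.zeros((50, 2))
        with pytest.raises(EmptyTrajectoryError):
            locomotion_metrics(make_traj(xy, likelihood=np.full(50, 0.2)))


class TestOccupancy:
    def test_stationary_mouse_single_bin(self):
        xy = np.tile([12.0, 33.0], (200, 1))
        occ = occupancy_map(make_traj(xy), arena_cm=40, bins=20)
        assert occ.sum() == 200
        assert (occ > 0).sum() == 1
        assert occ.max() == 200

    def test_sum_conservation_on_random_walk(self):
        traj = synth.make_trajectory(synth.WalkSpec(duration_s=20, seed=4, dropout_rate=0.0))
        occ = occupancy_map(traj, arena_cm=40, bins=16)
        valid = (traj.data["centroid_likelihood"] >= 0.9).sum()
        assert occ.sum() == valid

    def test_uniform_sweep_is_near_uniform(self):
        # serpentine sweep visiting every bin of a 4x4 grid equally
        pts = []
        for row in range(4):
            cols = range(4) if row % 2 == 0 else range(3, -1, -1)
            for col in cols:
                for _ in range(10):
                    pts.append((5 + 10 * col, 5 + 10 * row))
        occ = occupancy_map(make_traj(np.array(pts, dtype=float)), arena_cm=40, bins=4)
        assert (occ == 10).all()

    def test_outside_positions_clipped_with_warning(self):
        xy = np.tile([45.0, 20.0], (10, 1))  # outside a 40-cm arena
        with pytest.warns(UserWarning, match="clipped"):
            occ = occupancy_map(make_traj(xy), arena_cm=40, bins=8)
        assert occ.sum() == 10


class TestStraightWalkSegments:
    def test_straight_run_yields_consecutive_windows(self):
        spec = synth.WalkSpec(duration_s=10, fps=30, speed_cm_s=6, turn_sd_deg=0,
                              gait_amplitude_deg=0, dropout_rate=0.0, seed=2)
        wins = straight_walk_segments(synth.make_trajectory(spec))
        assert len(wins) == 5
        assert all(b - a == 30 for a, b in wins)
        starts = [a for a, _ in wins]
        assert starts == sorted(starts)

    def test_rotation_in_place_yields_none(self):
        th = np.linspace(0, 8 * np.pi, 300)
        xy = np.column_stack([20 + 0.3 * np.cos(th), 20 + 0.3 * np.sin(th)])
        with pytest.warns(UserWarning, match="straight-walk"):
            wins = straight_walk_segments(make_traj(xy))
        assert wins == []

    def test_windows_satisfy_selection_criteria_vs_exhaustive_scan(self):
        traj = synth.make_trajectory(
            synth.WalkSpec(duration_s=20, speed_cm_s=7, turn_sd_deg=60,
                           dropout_rate=0.0, seed=6)
        )
        wins = straight_walk_segments(traj, speed_min_cm_s=3.0, turn_max_deg_s=20.0)
        xy = traj.xy_cm("hip")
        fps = traj.fps
        # every reported window must pass the stated criteria, re-checked
        # by an independent scan
        for a, b in wins:
            seg = xy[a:b]
            steps = np.diff(seg, axis=0)
            path = np.linalg.norm(steps, axis=1).sum()
            assert path / ((b - a - 1) / fps) >= 3.0
            h0 = np.arctan2(steps[0, 1], steps[0, 0])
            h1 = np.arctan2(steps[-1, 1], steps[-1, 0])
            assert abs(np.angle(np.exp(1j * (h1 - h0)))) <= np.deg2rad(20.0) + 1e-9
        # windows are pairwise disjoint
        for i, w1 in enumerate(wins):
            for w2 in wins[i + 1 :]:
                assert w1[1] <= w2[0] or w2[1] <= w1[0]


class TestGait:
    def test_noiseless_cosine_recovered_exactly(self):
        spec = synth.WalkSpec(duration_s=20, fps=30, speed_cm_s=6, turn_sd_deg=0,
                              gait_amplitude_deg=12, gait_freq_hz=2.5,
                              dropout_rate=0.0, seed=2)
        traj = synth.make_trajectory(spec)
        fits, amp = gait_amplitude(traj)
        assert amp == pytest.approx(12.0, abs=0.1)
        for f in fits:
            assert f.freq_hz == pytest.approx(2.5, abs=0.05)
            assert f.r2 > 0.99

    def test_constant_angle_zero_amplitude(self):
        spec = synth.WalkSpec(duration_s=10, fps=30, speed_cm_s=5, turn_sd_deg=0,
                              gait_amplitude_deg=0, dropout_rate=0.0, seed=3)
        traj = synth.make_trajectory(spec)
        fits, amp = gait_amplitude(traj)
        assert amp == pytest.approx(0.0, abs=1e-4)

    def test_noisy_amplitude_recovered_within_one_degree(self):
        spec = synth.WalkSpec(duration_s=30, fps=30, speed_cm_s=6, turn_sd_deg=30,
                              gait_amplitude_deg=12, gait_freq_hz=2.5,
                              angle_noise_deg=2.0, dropout_rate=0.0, seed=3)
        traj = synth.make_trajectory(spec)
        _, amp = gait_amplitude(traj)
        assert amp == pytest.approx(12.0, abs=1.0)

    @pytest.mark.parametrize("amp_deg,freq_hz", [(6.0, 1.5), (12.0, 2.5), (20.0, 4.0)])
    def test_parameter_recovery_grid(self, amp_deg, freq_hz):
        spec = synth.WalkSpec(duration_s=20, fps=30, speed_cm_s=6, turn_sd_deg=20,
                              gait_amplitude_deg=amp_deg, gait_freq_hz=freq_hz,
                              angle_noise_deg=1.0, dropout_rate=0.0, seed=8)
        _, amp = gait_amplitude(synth.make_trajectory(spec))
        assert amp == pytest.approx(amp_deg, rel=0.10)

    def test_angle_series_matches_generator(self):
        spec = synth.WalkSpec(duration_s=5, fps=30, turn_sd_deg=0,
                              gait_amplitude_deg=10, gait_freq_hz=2.0,
                              angle_offset_deg=150.0, dropout_rate=0.0, seed=5)
        traj = synth.make_trajectory(spec)
        angle = body_segment_angle(traj)
        assert angle.min() >= 140.0 - 1e-6
        assert angle.max() <= 160.0 + 1e-6
        # discrete 30-fps sampling of a 2-Hz cosine misses the exact peaks
        assert np.ptp(angle) == pytest.approx(20.0, abs=0.3)


class TestGrip:
    def test_normalized_mean_force(self):
        assert grip_index([100, 110, 120], 25.0) == pytest.approx(4.4)

    def test_equal_forces_reduce_to_ratio(self):
        assert grip_index([80, 80, 80], 20.0) == pytest.approx(4.0)

    def test_trial_order_irrelevant(self):
        assert grip_index([90, 120, 100], 24.0) == grip_index([120, 100, 90], 24.0)

    @pytest.mark.parametrize("forces,weight", [([0, 100, 100], 25.0), ([100, 100, 100], 0.0)])
    def test_nonpositive_inputs_rejected(self, forces, weight):
        with pytest.raises(ValueError):
            grip_index(forces, weight)


class TestPoseTableIO:
    def test_dlc_csv_round_trip(self, tmp_path):
        traj = synth.make_trajectory(synth.WalkSpec(duration_s=3, seed=9))
        path = tmp_path / "traj.csv"
        traj.to_dlc_csv(path)
        # the dialect has exactly three header rows
        header = path.read_text().splitlines()[:3]
        assert header[0].startswith("scorer")
        assert "bodyparts" in header[1]
        assert "coords" in header[2]
        back = Trajectory.from_dlc_csv(path, fps=traj.fps, cm_per_px=traj.cm_per_px)
        for kp in traj.keypoints:
            np.testing.assert_allclose(
                back.data[f"{kp}_x"], traj.data[f"{kp}_x"], rtol=1e-9
            )
            np.testing.assert_allclose(
                back.data[f"{kp}_likelihood"], traj.data[f"{kp}_likelihood"], rtol=1e-9
            )
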