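"""Tracking loop: head state, head-pointing, benchmark update, prediction."""

import dataclasses
import math

import numpy as np
import pytest

from camgaze.features import LandmarkFrame, extract_eye_features
from camgaze.geometry import HeadPose, ScreenGeometry
from camgaze.simulator import (RigConfig, Scenario, ScenarioStream,
                               make_calibration_scenario, run_closed_loop)
from camgaze.calibration import default_calibration_dots, run_calibration
from camgaze.tracker import (GazeSample, TrackerConfig, TrackerState,
                             compute_head_pointing, detect_head_state,
                             predict_gaze, read_gaze_log, step,
                             update_pupil_benchmark, write_gaze_log)

SCREEN = ScreenGeometry(1920, 1080, 480.0, 270.0, 500.0)


class TestHeadState:
    REF = HeadPose(yaw=0.0, pitch=0.0)

    def test_small_deviation_is_fixed(self):
        assert detect_head_state(HeadPose(yaw=0.5, pitch=0.3), self.REF) == "fixed"

    def test_large_yaw_is_moving(self):
        assert detect_head_state(HeadPose(yaw=2.5), self.REF) == "moving"

    def test_boundary_is_fixed(self):
        assert detect_head_state(HeadPose(yaw=2.0), self.REF,
                                 threshold=2.0) == "fixed"


class TestHeadPointing:
    def test_zero_offset_case(self):
        # under the printed "+" pitch term, theta=theta0 and beta=-beta0
        # lands exactly on the screen center
        H, on = compute_head_pointing(HeadPose(yaw=3.0, pitch=-2.0),
                                      HeadPose(yaw=3.0, pitch=2.0), SCREEN)
        assert on
        assert np.allclose(H, SCREEN.center_px, atol=1e-9)

    def test_tan_oracle_value(self):
        # dx = 500 tan(10 deg) = 88.163 mm = 352.65 px at 0.25 mm/px
        H, on = compute_head_pointing(HeadPose(yaw=10.0), HeadPose(), SCREEN)
        dx_mm = 500.0 * math.tan(math.radians(10.0))
        assert on
        assert H[0] == pytest.approx(960.0 + dx_mm / 0.25, abs=1e-9)
        assert H[0] == pytest.approx(1312.65, abs=0.01)
        assert H[1] == pytest.approx(540.0)

    def test_out_of_screen_clamped_and_flagged(self):
        H, on = compute_head_pointing(HeadPose(yaw=45.0), HeadPose(), SCREEN)
        assert not on
        assert H[0] == 1919.0

    def test_pitch_mode_switch(self):
        pose, pose0 = HeadPose(pitch=4.0), HeadPose(pitch=1.0)
        Hp, _ = compute_head_pointing(pose, pose0, SCREEN, pitch_mode="printed")
        Hd, _ = compute_head_pointing(pose, pose0, SCREEN,
                                      pitch_mode="difference")
        d, py = 500.0, 0.25
        dy_p = d * (math.tan(math.radians(4)) + math.tan(math.radians(1)))
        dy_d = d * (math.tan(math.radians(4)) - math.tan(math.radians(1)))
        assert Hp[1] == pytest.approx(540.0 - dy_p / py, abs=1e-9)
        assert Hd[1] == pytest.approx(540.0 - dy_d / py, abs=1e-9)


class TestBenchmarkUpdate:
    def test_direct_equation(self):
        corners_cal = np.array([[50.0, 40.0], [30.0, 40.0],
                                [90.0, 40.0], [110.0, 40.0]])
        now = corners_cal + np.array([[10.0, 0.0], [12.0, 0.0],
                                      [4.0, 2.0], [6.0, 2.0]])
        feats = _features_with_corners(now)
        lc, rc = update_pupil_benchmark(feats, corners_cal,
                                        np.array([100.0, 50.0]),
                                        np.array([160.0, 50.0]))
        assert np.allclose(lc, (111.0, 50.0))   # (10 + 12)/2 = 11
        assert np.allclose(rc, (165.0, 52.0))   # (4 + 6)/2 = 5, dy = 2

    def test_zero_displacement_is_identity(self):
        corners = np.arange(8, dtype=float).reshape(4, 2)
        feats = _features_with_corners(corners)
        lc, rc = update_pupil_benchmark(feats, corners,
                                        np.array([1.0, 2.0]),
                                        np.array([3.0, 4.0]))
        assert np.allclose(lc, (1.0, 2.0)) and np.allclose(rc, (3.0, 4.0))

    def test_rig_rotation_benchmark_close_to_true_pupil(self, rig, calibration):
        """After a 10-degree yaw turn, the corner-updated benchmark must sit
        within 1.5 px of the rig's true pupil when fixating the new
        reference point."""
        pose = HeadPose(yaw=10.0)
        H, _ = compute_head_pointing(pose, calibration.benchmarks.head_pose0,
                                     rig.screen)
        scenario = Scenario(target_px=lambda t: H,
                            head_pose=lambda t: pose, duration_s=1.0)
        from camgaze.simulator import render_frame
        frame, _, _ = render_frame(scenario, 0.0, rig)
        feats = extract_eye_features(frame)
        lc_star, rc_star = update_pupil_benchmark(
            feats, calibration.benchmarks.corners,
            calibration.benchmarks.pupil_left,
            calibration.benchmarks.pupil_right)
        assert np.linalg.norm(lc_star - feats.pupil_left) < 1.5
        assert np.linalg.norm(rc_star - feats.pupil_right) < 1.5


class TestPredictGaze:
    def test_zero_deviation_returns_reference_point(self, calibration):
        state = TrackerState.from_calibration(calibration)
        feats = _features_with_pupils(state.pupil_left_bench,
                                      state.pupil_right_bench)
        sample = predict_gaze(feats, state, SCREEN)
        assert np.allclose(sample.gaze, state.reference_point)

    def test_equation_arithmetic(self, calibration):
        from camgaze.calibration import CalibrationResult
        clone = CalibrationResult.from_json(calibration.to_json())
        state = TrackerState.from_calibration(clone)
        scale = np.array([90.0, 90.0])
        object.__setattr__(state.calibration.scale, "left", scale)
        object.__setattr__(state.calibration.scale, "right", scale)
        state.reference_point = np.array([960.0, 540.0])
        feats = _features_with_pupils(state.pupil_left_bench + (2.0, 0.0),
                                      state.pupil_right_bench + (2.0, 0.0))
        sample = predict_gaze(feats, state, SCREEN)
        assert np.allclose(sample.gaze, (1140.0, 540.0))
        assert np.allclose(sample.gaze,
                           (sample.gaze_left + sample.gaze_right) / 2.0)


class TestStepLoop:
    def test_static_head_never_updates_benchmarks(self, rig, fixed_head_loop):
        res = fixed_head_loop
        assert all(s.head_state == "fixed" for s in res.samples if s.valid)
        refs = np.array([s.reference_point for s in res.samples])
        assert np.allclose(refs, rig.screen.center_px)

    def test_fixed_head_accuracy_is_sane(self, fixed_head_loop):
        assert fixed_head_loop.report["overall"]["mean_error_deg"] < 2.0

    def test_single_yaw_turn_state_machine(self, rig, calibration):
        def head(t):
            if t < 1.0:
                return HeadPose()
            if t < 1.3:
                w = (t - 1.0) / 0.3
                return HeadPose(yaw=8.0 * w * w * (3 - 2 * w))
            return HeadPose(yaw=8.0)

        target = rig.screen.center_px + np.array([200.0, 0.0])
        scenario = Scenario(target_px=lambda t: target, head_pose=head,
                            duration_s=3.0, sample_rate_hz=30)
        stream = ScenarioStream(scenario, rig)
        state = TrackerState.from_calibration(calibration)
        states = []
        for frame in stream.frames():
            sample, state = step(frame, state, rig.intrinsics, rig.screen,
                                 rig.face_model)
            states.append(sample.head_state)
        assert states[0] == "fixed"
        assert "moving" in states
        assert states[-1] == "fixed"
        expected_H, _ = compute_head_pointing(
            HeadPose(yaw=8.0), calibration.benchmarks.head_pose0, rig.screen)
        assert np.allclose(state.reference_point, expected_H, atol=1e-6)

    def test_missing_face_gives_invalid_sample(self, rig, calibration):
        state = TrackerState.from_calibration(calibration)
        bench_before = state.pupil_left_bench.copy()
        empty = LandmarkFrame(0.5, {}, 1280, 960, source="synthetic")
        sample, state = step(empty, state, rig.intrinsics, rig.screen)
        assert not sample.valid
        assert np.array_equal(state.pupil_left_bench, bench_before)

    def test_translation_equivariance_via_principal_point(self, rig):
        """Shifting the camera principal point translates every landmark but
        must leave predicted gaze unchanged."""
        shifted_intr = dataclasses.replace(rig.intrinsics,
                                           principal_x=rig.intrinsics.principal_x + 40.0,
                                           principal_y=rig.intrinsics.principal_y - 25.0)
        shifted_rig = dataclasses.replace(rig, intrinsics=shifted_intr)
        from camgaze.simulator import make_fixation_scenario
        base_sc = make_fixation_scenario(rig.screen, head_mode="fixed",
                                         rig=rig, dwell_s=1.0,
                                         sample_rate_hz=5)
        a = run_closed_loop(base_sc, rig, seed=2)
        b = run_closed_loop(base_sc, shifted_rig, seed=2)
        ga = np.array([s.gaze for s in a.samples])
        gb = np.array([s.gaze for s in b.samples])
        assert np.allclose(ga, gb, atol=1e-6)


class TestGazeLog:
    def test_bit_exact_round_trip_and_determinism(self, rig, calibration,
                                                  tmp_path):
        scenario = make_calibration_scenario(rig.screen, sample_rate_hz=10)
        from camgaze.tracker import track
        paths = []
        for name in ("a.csv", "b.csv"):
            samples = list(track(ScenarioStream(scenario, rig).frames(),
                                 calibration, rig.intrinsics, rig.screen))
            p = tmp_path / name
            write_gaze_log(samples, p, calibration=calibration,
                           screen=rig.screen, config=TrackerConfig())
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        back = read_gaze_log(paths[0])
        samples = list(track(ScenarioStream(scenario, rig).frames(),
                             calibration, rig.intrinsics, rig.screen))
        for s, r in zip(samples, back):
            assert r.timestamp == s.timestamp
            assert np.array_equal(r.gaze, s.gaze)
            assert r.head_state == s.head_state


def _features_with_corners(corners):
    from camgaze.features import EyeFeatures
    return EyeFeatures(np.zeros(2), np.zeros(2), corners[0], corners[1],
                       corners[2], corners[3], np.zeros((6, 2)))


def _features_with_pupils(left, right):
    from camgaze.features import EyeFeatures
    z = np.zeros(2)
    return EyeFeatures(np.asarray(left, dtype=float),
                       np.asarray(right, dtype=float), z, z, z, z,
                       np.zeros((6, 2)))
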