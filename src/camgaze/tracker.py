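"""Per-frame eye-tracking loop.

Pipeline per frame: extract features -> estimate head pose -> head-state
detection (2-degree dead-band against the pose of the current reference
point) -> while the head moves, recompute the head-pointing coordinate

    dx = d (tan theta - tan theta0),  dy = d (tan beta + tan beta0),
    H = (Ox + dx, Oy - dy)                      [mm terms scaled to px]

and shift the pupil-center benchmarks by the mean inner/outer eye-corner
displacement since calibration; when motion ceases, freeze the reference
point at the settled head-pointing -> predict the gaze point

    Lb = L - Lc*,  LG = H + Lb o Ls   (and RG analogously),
    gaze = (LG + RG) / 2.

The head-pose benchmark (theta0, beta0) always remains the calibration pose.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .calibration import CalibrationResult
from .errors import FeatureExtractionError, StreamError
from .features import FACE_MODEL_POINTS, EyeFeatures, LandmarkFrame, extract_eye_features
from .geometry import (CameraIntrinsics, HeadPose, PnPResult, ScreenGeometry,
                       estimate_head_pose)

__all__ = [
    "TrackerConfig",
    "TrackerState",
    "GazeSample",
    "detect_head_state",
    "compute_head_pointing",
    "update_pupil_benchmark",
    "predict_gaze",
    "step",
    "track",
    "write_gaze_log",
    "read_gaze_log",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable thresholds of the tracking loop.

    * ``head_state_threshold_deg`` — dead-band for declaring head motion
      (strictly greater than; default 2).
    * ``stop_delta_deg`` / ``stop_frames`` — motion is considered ended when
      the inter-frame pose change stays below ``stop_delta_deg`` for
      ``stop_frames`` consecutive frames.
    * ``pitch_mode`` — ``"printed"`` uses dy = d(tan b + tan b0);
      ``"difference"`` uses dy = d(tan b - tan b0).  Identical when the
      calibration pitch b0 is zero.
    * ``update_pupil_benchmarks`` — disable to ablate the eye-corner-based
      benchmark update (the pupil benchmarks then stay at calibration).
    * ``smoothing_window`` — optional moving-average over the last N valid
      gaze points; 0/1 disables (default).
    """

    head_state_threshold_deg: float = 2.0
    stop_delta_deg: float = 0.5
    stop_frames: int = 3
    pitch_mode: str = "printed"
    update_pupil_benchmarks: bool = True
    clamp_to_screen: bool = True
    smoothing_window: int = 0

    def to_dict(self) -> dict:
        return {
            "head_state_threshold_deg": self.head_state_threshold_deg,
            "stop_delta_deg": self.stop_delta_deg,
            "stop_frames": self.stop_frames,
            "pitch_mode": self.pitch_mode,
            "update_pupil_benchmarks": self.update_pupil_benchmarks,
            "clamp_to_screen": self.clamp_to_screen,
            "smoothing_window": self.smoothing_window,
        }


@dataclass
class GazeSample:
    """Per-frame gaze prediction."""

    timestamp: float
    gaze: np.ndarray
    gaze_left: np.ndarray
    gaze_right: np.ndarray
    head_state: str                  # "fixed" | "moving"
    reference_point: np.ndarray
    valid: bool = True
    on_screen: bool = True
    deviation_left: np.ndarray = field(default_factory=lambda: np.zeros(2))
    deviation_right: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @classmethod
    def invalid(cls, timestamp: float, reference_point: np.ndarray) -> "GazeSample":
        nan2 = np.full(2, np.nan)
        return cls(timestamp, nan2.copy(), nan2.copy(), nan2.copy(), "fixed",
                   np.asarray(reference_point, dtype=float), valid=False,
                   on_screen=False)


@dataclass
class TrackerState:
    """Mutable tracking state: current benchmarks and the motion machine."""

    calibration: CalibrationResult
    config: TrackerConfig
    reference_point: np.ndarray
    ref_pose: HeadPose
    pupil_left_bench: np.ndarray     # Lc*
    pupil_right_bench: np.ndarray    # Rc*
    head_state: str = "fixed"
    last_pose: HeadPose | None = None
    still_count: int = 0
    pnp_cache: PnPResult | None = None
    _smooth_buf: deque = field(default_factory=deque)

    @classmethod
    def from_calibration(cls, calibration: CalibrationResult,
                         config: TrackerConfig | None = None) -> "TrackerState":
        config = config or TrackerConfig()
        b = calibration.benchmarks
        return cls(
            calibration=calibration,
            config=config,
            reference_point=np.array(b.reference_point, dtype=float),
            ref_pose=b.head_pose0,
            pupil_left_bench=np.array(b.pupil_left, dtype=float),
            pupil_right_bench=np.array(b.pupil_right, dtype=float),
        )


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def detect_head_state(pose: HeadPose, ref_pose: HeadPose,
                      threshold: float = 2.0) -> str:
    """``"moving"`` iff max(|yaw dev|, |pitch dev|) strictly exceeds the
    threshold, measured against the pose of the current reference point."""
    dev = max(abs(pose.yaw - ref_pose.yaw), abs(pose.pitch - ref_pose.pitch))
    return "moving" if dev > threshold else "fixed"


def compute_head_pointing(
    pose: HeadPose,
    pose0: HeadPose,
    screen: ScreenGeometry,
    pitch_mode: str = "printed",
    clamp: bool = True,
) -> tuple[np.ndarray, bool]:
    """Screen coordinate the head's facing direction intersects.

    Returns ``(H_px, on_screen)``; an off-screen H is clamped to the screen
    bounds and flagged ``on_screen=False`` (when ``clamp`` is set).
    """
    d = screen.viewing_distance_mm
    th, th0 = np.radians(pose.yaw), np.radians(pose0.yaw)
    be, be0 = np.radians(pose.pitch), np.radians(pose0.pitch)
    dx = d * (np.tan(th) - np.tan(th0))
    if pitch_mode == "printed":
        dy = d * (np.tan(be) + np.tan(be0))
    elif pitch_mode == "difference":
        dy = d * (np.tan(be) - np.tan(be0))
    else:
        raise ValueError(f"pitch_mode must be 'printed' or 'difference': {pitch_mode!r}")
    ox, oy = screen.center_px
    H = np.array([ox + dx / screen.pitch_x, oy - dy / screen.pitch_y])
    lo = np.zeros(2)
    hi = np.array([screen.res_x - 1.0, screen.res_y - 1.0])
    on_screen = bool(np.all(H >= lo) and np.all(H <= hi))
    if clamp and not on_screen:
        H = np.clip(H, lo, hi)
    return H, on_screen


def update_pupil_benchmark(
    features_now: EyeFeatures,
    corners_cal: np.ndarray,
    pupil_left_cal: np.ndarray,
    pupil_right_cal: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift each eye's calibration pupil benchmark by the mean signed
    displacement of that eye's inner and outer corners since calibration.

    ``corners_cal`` rows: inner-left, outer-left, inner-right, outer-right.
    """
    now = features_now.corners()
    disp = now - np.asarray(corners_cal, dtype=float)
    lc_star = np.asarray(pupil_left_cal, dtype=float) + disp[:2].mean(axis=0)
    rc_star = np.asarray(pupil_right_cal, dtype=float) + disp[2:].mean(axis=0)
    return lc_star, rc_star


def predict_gaze(features: EyeFeatures, state: TrackerState,
                 screen: ScreenGeometry, timestamp: float = 0.0) -> GazeSample:
    """Map pupil deviations from the current benchmarks to a screen point."""
    lb = features.pupil_left - state.pupil_left_bench
    rb = features.pupil_right - state.pupil_right_bench
    H = state.reference_point
    lg = H + lb * state.calibration.scale.left
    rg = H + rb * state.calibration.scale.right
    gaze = (lg + rg) / 2.0
    lo = np.zeros(2)
    hi = np.array([screen.res_x - 1.0, screen.res_y - 1.0])
    on_screen = bool(np.all(gaze >= lo) and np.all(gaze <= hi))
    if state.config.clamp_to_screen and not on_screen:
        gaze = np.clip(gaze, lo, hi)
    return GazeSample(
        timestamp=timestamp,
        gaze=gaze,
        gaze_left=lg,
        gaze_right=rg,
        head_state=state.head_state,
        reference_point=H.copy(),
        valid=True,
        on_screen=on_screen,
        deviation_left=lb,
        deviation_right=rb,
    )


# --------------------------------------------------------------------------
# the per-frame loop
# --------------------------------------------------------------------------


def step(
    frame: LandmarkFrame,
    state: TrackerState,
    intrinsics: CameraIntrinsics,
    screen: ScreenGeometry,
    face_model: np.ndarray = FACE_MODEL_POINTS,
) -> tuple[GazeSample, TrackerState]:
    """Process one frame, returning the gaze sample and the updated state.

    Feature or pose failures yield an invalid sample and leave the state
    untouched.  ``state`` is mutated in place and also returned.
    """
    cfg = state.config
    try:
        features = extract_eye_features(frame)
    except FeatureExtractionError:
        return GazeSample.invalid(frame.timestamp, state.reference_point), state
    pose, pnp = estimate_head_pose(features.pnp_points, face_model, intrinsics,
                                   initial=state.pnp_cache)
    if not pose.valid:
        return GazeSample.invalid(frame.timestamp, state.reference_point), state
    state.pnp_cache = pnp

    cal = state.calibration
    if state.head_state == "fixed":
        if detect_head_state(pose, state.ref_pose,
                             cfg.head_state_threshold_deg) == "moving":
            state.head_state = "moving"
            state.still_count = 0

    if state.head_state == "moving":
        # recompute head-pointing and pupil benchmarks every frame so gaze
        # output never pauses during motion
        H, _ = compute_head_pointing(pose, cal.benchmarks.head_pose0, screen,
                                     pitch_mode=cfg.pitch_mode,
                                     clamp=cfg.clamp_to_screen)
        state.reference_point = H
        if cfg.update_pupil_benchmarks:
            state.pupil_left_bench, state.pupil_right_bench = update_pupil_benchmark(
                features, cal.benchmarks.corners,
                cal.benchmarks.pupil_left, cal.benchmarks.pupil_right)
        if state.last_pose is not None:
            delta = max(abs(pose.yaw - state.last_pose.yaw),
                        abs(pose.pitch - state.last_pose.pitch))
            state.still_count = state.still_count + 1 if delta < cfg.stop_delta_deg else 0
        if state.still_count >= cfg.stop_frames:
            # motion ended: freeze the reference point at the settled
            # head-pointing and re-anchor the dead-band at the settled pose
            state.head_state = "fixed"
            state.ref_pose = pose
            state.still_count = 0

    sample = predict_gaze(features, state, screen, timestamp=frame.timestamp)
    state.last_pose = pose

    if cfg.smoothing_window > 1:
        state._smooth_buf.append(sample.gaze.copy())
        while len(state._smooth_buf) > cfg.smoothing_window:
            state._smooth_buf.popleft()
        sample.gaze = np.mean(state._smooth_buf, axis=0)
    return sample, state


def track(
    stream: Iterable[LandmarkFrame],
    calibration: CalibrationResult,
    intrinsics: CameraIntrinsics,
    screen: ScreenGeometry,
    config: TrackerConfig | None = None,
    face_model: np.ndarray = FACE_MODEL_POINTS,
) -> Iterator[GazeSample]:
    """Run the tracking loop over a whole landmark stream."""
    state = TrackerState.from_calibration(calibration, config)
    for frame in stream:
        sample, state = step(frame, state, intrinsics, screen, face_model)
        yield sample


# --------------------------------------------------------------------------
# gaze log I/O
# --------------------------------------------------------------------------

_GAZE_COLUMNS = ("timestamp_s,gaze_x_px,gaze_y_px,gaze_left_x,gaze_left_y,"
                 "gaze_right_x,gaze_right_y,head_state,ref_x,ref_y,valid")


def write_gaze_log(samples: Iterable[GazeSample], csv_path,
                   calibration: CalibrationResult | None = None,
                   screen: ScreenGeometry | None = None,
                   config: TrackerConfig | None = None) -> None:
    """CSV gaze log plus JSON sidecar; floats via ``repr`` for a bit-exact
    round trip."""
    csv_path = Path(csv_path)
    with open(csv_path, "w") as fh:
        fh.write(_GAZE_COLUMNS + "\n")
        for s in samples:
            row = [repr(float(s.timestamp))]
            for vec in (s.gaze, s.gaze_left, s.gaze_right):
                row += [repr(float(vec[0])), repr(float(vec[1]))]
            row += [s.head_state,
                    repr(float(s.reference_point[0])),
                    repr(float(s.reference_point[1])),
                    "1" if s.valid else "0"]
            fh.write(",".join(row) + "\n")
    sidecar = {
        "calibration_hash": calibration.content_hash() if calibration else None,
        "screen": screen.to_dict() if screen else None,
        "config": config.to_dict() if config else None,
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_gaze_log(csv_path) -> list[GazeSample]:
    csv_path = Path(csv_path)
    samples = []
    with open(csv_path) as fh:
        header = fh.readline().strip()
        if header != _GAZE_COLUMNS:
            raise StreamError(f"unexpected gaze log header: {header}")
        for line in fh:
            f = line.rstrip("\n").split(",")
            samples.append(GazeSample(
                timestamp=float(f[0]),
                gaze=np.array([float(f[1]), float(f[2])]),
                gaze_left=np.array([float(f[3]), float(f[4])]),
                gaze_right=np.array([float(f[5]), float(f[6])]),
                head_state=f[7],
                reference_point=np.array([float(f[8]), float(f[9])]),
                valid=f[10] == "1",
            ))
    return samples
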