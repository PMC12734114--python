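"""Five-point gaze calibration.

The user fixates five on-screen dots (center, top, left, bottom, right) for
about 2 s each.  Per dot, every feature is averaged over the final 0.5 s of
the dwell.  The center dot supplies the benchmarks (reference point = screen
center, pupil centers, eye corners, head pose); the four edge dots supply the
per-eye scale coefficients mapping pupil-center image displacement to screen
displacement:

    Ls = ( (C5x - C3x)/(L5x - L3x), (C4y - C2y)/(L4y - L2y) )

and analogously Rs for the right eye.  Calibration is rejected when the head
pose varies across dots beyond a threshold (default 2 degrees, the same
dead-band the tracker uses).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import CalibrationError
from .features import FACE_MODEL_POINTS, EyeFeatures, LandmarkFrame, extract_eye_features
from .geometry import (CameraIntrinsics, HeadPose, ScreenGeometry,
                       estimate_head_pose)

__all__ = [
    "CalibrationDot",
    "ScaleCoefficients",
    "Benchmarks",
    "CalibrationResult",
    "default_calibration_dots",
    "aggregate_dot_features",
    "compute_scale_coefficients",
    "validate_head_stability",
    "run_calibration",
]

DEFAULT_DWELL_S = 2.0
DEFAULT_WINDOW_S = 0.5
DEFAULT_STABILITY_DEG = 2.0
DEFAULT_EDGE_MARGIN_PX = 30.0
SCALE_SANITY_RANGE = (5.0, 500.0)


@dataclass(frozen=True)
class CalibrationDot:
    """One calibration target: 1=center, 2=top, 3=left, 4=bottom, 5=right."""

    index: int
    screen_position: np.ndarray

    def __post_init__(self):
        if not 1 <= self.index <= 5:
            raise CalibrationError(f"dot index must be 1..5, got {self.index}")


def default_calibration_dots(screen: ScreenGeometry,
                             margin_px: float = DEFAULT_EDGE_MARGIN_PX
                             ) -> list[CalibrationDot]:
    """Center dot plus four edge dots ``margin_px`` from each screen edge."""
    cx, cy = screen.center_px
    return [
        CalibrationDot(1, np.array([cx, cy])),
        CalibrationDot(2, np.array([cx, margin_px])),
        CalibrationDot(3, np.array([margin_px, cy])),
        CalibrationDot(4, np.array([cx, screen.res_y - margin_px])),
        CalibrationDot(5, np.array([screen.res_x - margin_px, cy])),
    ]


@dataclass(frozen=True)
class ScaleCoefficients:
    """Per-eye, per-axis screen-px per image-px ratios (Ls, Rs)."""

    left: np.ndarray   # (sx, sy)
    right: np.ndarray

    def to_dict(self) -> dict:
        return {"left": [float(v) for v in self.left],
                "right": [float(v) for v in self.right]}

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleCoefficients":
        return cls(left=np.array(d["left"], dtype=float),
                   right=np.array(d["right"], dtype=float))


@dataclass
class Benchmarks:
    """Reference quantities against which per-frame deviations are measured.

    ``reference_point`` and the pupil benchmarks are updated by the tracker
    after head motion; the eye-corner set and ``head_pose0`` stay fixed at
    their calibration values.
    """

    reference_point: np.ndarray          # screen px
    pupil_left: np.ndarray               # Lc, image px
    pupil_right: np.ndarray              # Rc, image px
    corners: np.ndarray                  # (4,2): inner-L, outer-L, inner-R, outer-R
    head_pose0: HeadPose                 # theta0, beta0

    def to_dict(self) -> dict:
        return {
            "reference_point": [float(v) for v in self.reference_point],
            "pupil_left": [float(v) for v in self.pupil_left],
            "pupil_right": [float(v) for v in self.pupil_right],
            "corners": [[float(v) for v in row] for row in self.corners],
            "head_pose0": {"yaw": self.head_pose0.yaw, "pitch": self.head_pose0.pitch,
                           "roll": self.head_pose0.roll},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Benchmarks":
        hp = d["head_pose0"]
        return cls(
            reference_point=np.array(d["reference_point"], dtype=float),
            pupil_left=np.array(d["pupil_left"], dtype=float),
            pupil_right=np.array(d["pupil_right"], dtype=float),
            corners=np.array(d["corners"], dtype=float),
            head_pose0=HeadPose(pitch=hp["pitch"], yaw=hp["yaw"], roll=hp["roll"]),
        )


@dataclass
class CalibrationResult:
    benchmarks: Benchmarks
    scale: ScaleCoefficients
    per_dot: list[dict] = field(default_factory=list)
    stability_ok: bool = True
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "benchmarks": self.benchmarks.to_dict(),
            "scale": self.scale.to_dict(),
            "per_dot": self.per_dot,
            "stability_ok": bool(self.stability_ok),
            "config": self.config,
        }
        text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "CalibrationResult":
        try:
            payload = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                payload = json.load(fh)
        return cls(
            benchmarks=Benchmarks.from_dict(payload["benchmarks"]),
            scale=ScaleCoefficients.from_dict(payload["scale"]),
            per_dot=payload.get("per_dot", []),
            stability_ok=payload.get("stability_ok", True),
            config=payload.get("config", {}),
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def aggregate_dot_features(
    samples: Sequence[tuple[float, EyeFeatures, HeadPose]],
    dwell: float = DEFAULT_DWELL_S,
    window: float = DEFAULT_WINDOW_S,
) -> tuple[EyeFeatures, HeadPose]:
    """Mean of every feature over the final ``window`` seconds of the dwell.

    ``samples`` timestamps are relative to dot onset; the averaging window is
    ``[dwell - window, dwell]``.  An empty window is a calibration failure.
    """
    selected = [(f, p) for t, f, p in samples if t >= dwell - window]
    if not selected:
        raise CalibrationError(
            f"no samples inside the final {window} s aggregation window")
    feats = [f for f, _ in selected]
    poses = [p for _, p in selected]

    def mean_of(attr):
        return np.mean([getattr(f, attr) for f in feats], axis=0)

    agg_features = EyeFeatures(
        pupil_left=mean_of("pupil_left"),
        pupil_right=mean_of("pupil_right"),
        inner_corner_left=mean_of("inner_corner_left"),
        outer_corner_left=mean_of("outer_corner_left"),
        inner_corner_right=mean_of("inner_corner_right"),
        outer_corner_right=mean_of("outer_corner_right"),
        pnp_points=mean_of("pnp_points"),
    )
    agg_pose = HeadPose(
        pitch=float(np.mean([p.pitch for p in poses])),
        yaw=float(np.mean([p.yaw for p in poses])),
        roll=float(np.mean([p.roll for p in poses])),
    )
    return agg_features, agg_pose


def compute_scale_coefficients(
    dots: dict[int, np.ndarray],
    pupils_left: dict[int, np.ndarray],
    pupils_right: dict[int, np.ndarray],
    sanity_range: tuple[float, float] = SCALE_SANITY_RANGE,
) -> ScaleCoefficients:
    """Scale coefficients Ls, Rs from the four edge dots (indices 2..5)."""
    for d in (dots, pupils_left, pupils_right):
        missing = {2, 3, 4, 5} - set(d)
        if missing:
            raise CalibrationError(f"edge dots {sorted(missing)} missing")

    def one_eye(p):
        dx_p = p[5][0] - p[3][0]
        dy_p = p[4][1] - p[2][1]
        if abs(dx_p) < 1e-12 or abs(dy_p) < 1e-12:
            raise CalibrationError("zero pupil displacement between edge dots")
        return np.array([
            (dots[5][0] - dots[3][0]) / dx_p,
            (dots[4][1] - dots[2][1]) / dy_p,
        ])

    scale = ScaleCoefficients(left=one_eye(pupils_left), right=one_eye(pupils_right))
    lo, hi = sanity_range
    mags = np.abs(np.concatenate([scale.left, scale.right]))
    if sanity_range is not None and (np.any(mags < lo) or np.any(mags > hi)):
        raise CalibrationError(
            f"scale coefficients {mags} outside sanity range [{lo}, {hi}]")
    return scale


def validate_head_stability(poses: Sequence[HeadPose],
                            threshold: float = DEFAULT_STABILITY_DEG) -> bool:
    """True unless any dot's yaw/pitch deviates from dot 1 by more than
    ``threshold`` degrees (strictly greater; roll is ignored)."""
    ref = poses[0]
    for p in poses[1:]:
        if max(abs(p.yaw - ref.yaw), abs(p.pitch - ref.pitch)) > threshold:
            return False
    return True


def run_calibration(
    stream: Iterable[LandmarkFrame],
    dots: Sequence[CalibrationDot],
    screen: ScreenGeometry,
    intrinsics: CameraIntrinsics,
    dwell: float = DEFAULT_DWELL_S,
    window: float = DEFAULT_WINDOW_S,
    stability_threshold: float = DEFAULT_STABILITY_DEG,
    face_model: np.ndarray = FACE_MODEL_POINTS,
) -> CalibrationResult:
    """Consume a landmark stream covering the five dots in order and build a
    :class:`CalibrationResult`.

    Frames are assigned to dots by timestamp: dot ``i`` (1-based, in the given
    order) owns ``[ (i-1)*dwell, i*dwell )`` relative to the first frame.
    Raises :class:`CalibrationError` on insufficient samples at any dot or on
    a head-stability failure (the user must recalibrate).
    """
    if len(dots) != 5 or sorted(d.index for d in dots) != [1, 2, 3, 4, 5]:
        raise CalibrationError("calibration needs the five dots indexed 1..5")
    by_dot: dict[int, list] = {d.index: [] for d in dots}
    order = [d.index for d in dots]
    t0 = None
    pnp_cache = None
    for frame in stream:
        if t0 is None:
            t0 = frame.timestamp
        rel = frame.timestamp - t0
        slot = int(rel // dwell)
        if slot >= len(order):
            break
        features = extract_eye_features(frame)
        pose, pnp_cache = estimate_head_pose(features.pnp_points, face_model,
                                             intrinsics, initial=pnp_cache)
        if not pose.valid:
            continue
        by_dot[order[slot]].append((rel - slot * dwell, features, pose))

    aggregated: dict[int, tuple[EyeFeatures, HeadPose]] = {}
    for idx in order:
        if not by_dot[idx]:
            raise CalibrationError(f"no samples observed at calibration dot {idx}")
        aggregated[idx] = aggregate_dot_features(by_dot[idx], dwell=dwell,
                                                 window=window)

    poses = [aggregated[i][1] for i in [1, 2, 3, 4, 5]]
    stable = validate_head_stability(poses, threshold=stability_threshold)
    dot_pos = {d.index: np.asarray(d.screen_position, dtype=float) for d in dots}
    scale = compute_scale_coefficients(
        dot_pos,
        {i: aggregated[i][0].pupil_left for i in [2, 3, 4, 5]},
        {i: aggregated[i][0].pupil_right for i in [2, 3, 4, 5]},
    )
    center_features, center_pose = aggregated[1]
    benchmarks = Benchmarks(
        reference_point=screen.center_px,
        pupil_left=center_features.pupil_left,
        pupil_right=center_features.pupil_right,
        corners=center_features.corners(),
        head_pose0=center_pose,
    )
    per_dot = [
        {
            "index": i,
            "screen_position": [float(v) for v in dot_pos[i]],
            "pupil_left": [float(v) for v in aggregated[i][0].pupil_left],
            "pupil_right": [float(v) for v in aggregated[i][0].pupil_right],
            "yaw": aggregated[i][1].yaw,
            "pitch": aggregated[i][1].pitch,
            "n_samples": len(by_dot[i]),
        }
        for i in [1, 2, 3, 4, 5]
    ]
    result = CalibrationResult(
        benchmarks=benchmarks,
        scale=scale,
        per_dot=per_dot,
        stability_ok=stable,
        config={"dwell_s": dwell, "window_s": window,
                "stability_threshold_deg": stability_threshold},
    )
    if not stable:
        err = CalibrationError(
            "head moved during calibration beyond "
            f"{stability_threshold} degrees; please recalibrate")
        err.result = result
        raise err
    return result
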