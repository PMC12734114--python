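"""Synthetic head/eye rig.

A rigid head (the package's six-point face model plus eye corners and two
eyeballs) sits in front of a screen and is observed by a pinhole webcam.
Per frame the head is rotated about a neck pivot according to the scenario's
head-pose trajectory, each eyeball is oriented so its optical axis passes
through the current on-screen target, the pupil is placed on the eyeball
sphere, and every consumed landmark is projected through the camera (with
optional i.i.d. Gaussian pixel jitter).

World frame: screen top-left corner, x right, y down (mm), z from the screen
toward the user; the screen is the plane z = 0.  The default camera sits at
the top-center of the screen with its axes aligned to the world frame, so a
neutral screen-facing head reads as yaw = pitch = roll = 0.

The rig supplies ground truth (target position and commanded head pose) for
every frame, which makes closed-loop evaluation of the whole tracking
pipeline possible without a camera or human subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .calibration import (CalibrationDot, CalibrationResult,
                          default_calibration_dots, run_calibration)
from .errors import RenderError
from .features import (FACE_MODEL_POINTS, LANDMARK_INDICES, PNP_LANDMARK_IDS,
                       LandmarkFrame)
from .geometry import (CameraIntrinsics, GeometryError, HeadPose,
                       ScreenGeometry, euler_to_matrix, mm_to_px,
                       project_points, px_to_mm)
from .metrics import accuracy_report
from .tracker import GazeSample, TrackerConfig, TrackerState, step

__all__ = [
    "RigConfig",
    "Scenario",
    "ScenarioStream",
    "render_frame",
    "make_fixation_scenario",
    "make_pursuit_scenario",
    "make_calibration_scenario",
    "run_closed_loop",
    "ClosedLoopResult",
    "DEFAULT_SCREEN",
    "DEFAULT_INTRINSICS",
]

#: Default evaluation screen: 1920x1080 at 0.25 mm/px, viewed from 500 mm.
DEFAULT_SCREEN = ScreenGeometry(res_x=1920, res_y=1080, width_mm=480.0,
                                height_mm=270.0, viewing_distance_mm=500.0)

#: Default rig camera: a wide-angle 1280x960 pinhole with no distortion.
DEFAULT_INTRINSICS = CameraIntrinsics(
    focal_x=800.0, focal_y=800.0, principal_x=640.0, principal_y=480.0,
    image_width=1280, image_height=960,
)

# additional rigid head-frame points (mm; nose tip at origin, x right, y down,
# z toward the back of the head).  Inner corners sit in the corneal plane
# (z = 3, like the outer corners of the face model) so that corner landmarks
# displace like the pupil under rigid head motion.
_INNER_CORNER_LEFT = np.array([-15.0, -35.0, 3.0])
_INNER_CORNER_RIGHT = np.array([15.0, -35.0, 3.0])
_EYEBALL_LEFT = np.array([-32.0, -35.0, 15.0])
_EYEBALL_RIGHT = np.array([32.0, -35.0, 15.0])


@dataclass(frozen=True)
class RigConfig:
    """Geometry of the synthetic head, camera and screen."""

    screen: ScreenGeometry = DEFAULT_SCREEN
    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
    face_model: np.ndarray = field(default_factory=lambda: FACE_MODEL_POINTS.copy())
    eyeball_left: np.ndarray = field(default_factory=lambda: _EYEBALL_LEFT.copy())
    eyeball_right: np.ndarray = field(default_factory=lambda: _EYEBALL_RIGHT.copy())
    inner_corner_left: np.ndarray = field(default_factory=lambda: _INNER_CORNER_LEFT.copy())
    inner_corner_right: np.ndarray = field(default_factory=lambda: _INNER_CORNER_RIGHT.copy())
    eyeball_radius_mm: float = 12.0
    iris_radius_mm: float = 4.0
    #: world position of the head origin (nose tip) at rest; the default puts
    #: the eyes at screen-center height, nose-to-screen = viewing distance
    head_position_mm: np.ndarray | None = None
    #: neck pivot in head frame: below and behind the face-model origin
    neck_pivot_mm: np.ndarray = field(default_factory=lambda: np.array([0.0, 80.0, 80.0]))
    #: camera pinhole position in world mm (default top-center of the screen)
    camera_position_mm: np.ndarray | None = None
    #: world->camera rotation (default identity: axes aligned with the screen)
    camera_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def resolved_head_position(self) -> np.ndarray:
        if self.head_position_mm is not None:
            return np.asarray(self.head_position_mm, dtype=float)
        s = self.screen
        # eyes are 35 mm above the nose in the head frame
        return np.array([s.width_mm / 2.0, s.height_mm / 2.0 + 35.0,
                         s.viewing_distance_mm])

    def resolved_camera_position(self) -> np.ndarray:
        if self.camera_position_mm is not None:
            return np.asarray(self.camera_position_mm, dtype=float)
        return np.array([self.screen.width_mm / 2.0, 0.0, 0.0])


@dataclass
class Scenario:
    """Target + head trajectories with schedule metadata."""

    target_px: Callable[[float], np.ndarray]
    head_pose: Callable[[float], HeadPose]
    duration_s: float
    sample_rate_hz: float = 30.0
    kind: str = "custom"
    #: for dotted tasks: list of (dot_index, start_s, end_s, (x_px, y_px))
    schedule: list = field(default_factory=list)

    def target_id(self, t: float) -> int:
        for idx, start, end, _pos in self.schedule:
            if start <= t < end:
                return idx
        return -1

    def times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sample_rate_hz))
        return np.arange(n) / self.sample_rate_hz


# --------------------------------------------------------------------------
# forward rendering
# --------------------------------------------------------------------------


def _head_to_world(points_head: np.ndarray, pose: HeadPose,
                   rig: RigConfig) -> np.ndarray:
    """Rigid head transform: rotation about the neck pivot."""
    R = euler_to_matrix(pose.yaw, pose.pitch, pose.roll)
    origin = rig.resolved_head_position()
    pivot = rig.neck_pivot_mm
    return origin + pivot + (np.atleast_2d(points_head) - pivot) @ R.T


def _project_world(points_world: np.ndarray, rig: RigConfig) -> np.ndarray:
    cam = (np.atleast_2d(points_world) - rig.resolved_camera_position()) \
        @ rig.camera_rotation.T
    try:
        return project_points(cam, rig.intrinsics)
    except GeometryError as exc:
        raise RenderError(str(exc)) from exc


def _iris_ring(pupil_w: np.ndarray, gaze_dir: np.ndarray,
               radius: float) -> np.ndarray:
    """Four points around the pupil in the plane perpendicular to the gaze."""
    up = np.array([0.0, 1.0, 0.0])
    u = np.cross(gaze_dir, up)
    u = u / np.linalg.norm(u)
    v = np.cross(gaze_dir, u)
    ring = []
    for ang in (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi):
        ring.append(pupil_w + radius * (np.cos(ang) * u + np.sin(ang) * v))
    return np.array(ring)


def render_frame(
    scenario: Scenario,
    t: float,
    rig: RigConfig,
    rng: np.random.Generator | None = None,
    noise_sigma_px: float = 0.0,
) -> tuple[LandmarkFrame, np.ndarray, HeadPose]:
    """Render the landmark frame at time ``t``.

    Returns ``(frame, true_target_px, true_head_pose)``.  Noise is additive
    isotropic Gaussian on every landmark independently, drawn from ``rng``.
    """
    if not (0.0 <= t <= scenario.duration_s):
        raise RenderError(f"t={t} outside scenario duration {scenario.duration_s}")
    pose = scenario.head_pose(t)
    target_px = np.asarray(scenario.target_px(t), dtype=float)
    target_w = np.append(px_to_mm(target_px, rig.screen), 0.0)

    face_w = _head_to_world(rig.face_model, pose, rig)
    inner_w = _head_to_world(
        np.vstack([rig.inner_corner_left, rig.inner_corner_right]), pose, rig)
    eyeballs_w = _head_to_world(
        np.vstack([rig.eyeball_left, rig.eyeball_right]), pose, rig)

    pupils_w, rings_w = [], []
    for eye_w in eyeballs_w:
        gaze_dir = target_w - eye_w
        norm = np.linalg.norm(gaze_dir)
        if norm <= rig.eyeball_radius_mm:
            raise RenderError("target inside the eyeball")
        gaze_dir = gaze_dir / norm
        pupil_w = eye_w + rig.eyeball_radius_mm * gaze_dir
        pupils_w.append(pupil_w)
        rings_w.append(_iris_ring(pupil_w, gaze_dir, rig.iris_radius_mm))

    idx = LANDMARK_INDICES
    world_points = {}
    for lid, row in zip(PNP_LANDMARK_IDS, face_w):
        world_points[lid] = row
    world_points[idx["left_eye_inner"]] = inner_w[0]
    world_points[idx["right_eye_inner"]] = inner_w[1]
    world_points[idx["left_iris_center"]] = pupils_w[0]
    world_points[idx["right_iris_center"]] = pupils_w[1]
    for base, ring in zip((idx["left_iris_center"], idx["right_iris_center"]),
                          rings_w):
        for k, p in enumerate(ring, start=1):
            world_points[base + k] = p

    lids = sorted(world_points)
    img = _project_world(np.array([world_points[l] for l in lids]), rig)
    if noise_sigma_px > 0:
        if rng is None:
            raise RenderError("noise requested but no random generator supplied")
        img = img + rng.normal(0.0, noise_sigma_px, size=img.shape)
    frame = LandmarkFrame(
        timestamp=t,
        points={l: img[k] for k, l in enumerate(lids)},
        image_width=rig.intrinsics.image_width,
        image_height=rig.intrinsics.image_height,
        source="synthetic",
    )
    return frame, target_px, pose


@dataclass
class ScenarioStream:
    """Landmark source over a scenario; satisfies the backend protocol."""

    scenario: Scenario
    rig: RigConfig
    noise_sigma_px: float = 0.0
    seed: int = 0
    t_offset: float = 0.0

    def frames(self) -> Iterator[LandmarkFrame]:
        rng = np.random.default_rng(self.seed)
        for t in self.scenario.times():
            frame, _, _ = render_frame(self.scenario, t, self.rig, rng,
                                       self.noise_sigma_px)
            frame.timestamp = t + self.t_offset
            yield frame

    def truth(self) -> tuple[np.ndarray, list[HeadPose], np.ndarray]:
        """(targets_px (N,2), poses, target_ids (N,)) aligned with frames()."""
        targets, poses, ids = [], [], []
        for t in self.scenario.times():
            targets.append(np.asarray(self.scenario.target_px(t), dtype=float))
            poses.append(self.scenario.head_pose(t))
            ids.append(self.scenario.target_id(t))
        return np.array(targets), poses, np.array(ids)


# --------------------------------------------------------------------------
# scenario factories
# --------------------------------------------------------------------------

YAW_LIMIT_DEG = 18.0
PITCH_LIMIT_DEG = 10.0


def _head_angles_toward(target_px: np.ndarray, rig: RigConfig,
                        fraction: float) -> tuple[float, float]:
    """Partial head rotation toward a screen target, clipped to the task's
    +-18 deg yaw / +-10 deg pitch range."""
    eye_mid = 0.5 * (rig.eyeball_left + rig.eyeball_right) + \
        rig.resolved_head_position()
    t_mm = px_to_mm(target_px, rig.screen)
    yaw_full = np.degrees(np.arctan2(t_mm[0] - eye_mid[0], eye_mid[2]))
    pitch_full = np.degrees(np.arctan2(-(t_mm[1] - eye_mid[1]), eye_mid[2]))
    yaw = float(np.clip(fraction * yaw_full, -YAW_LIMIT_DEG, YAW_LIMIT_DEG))
    pitch = float(np.clip(fraction * pitch_full, -PITCH_LIMIT_DEG, PITCH_LIMIT_DEG))
    return yaw, pitch


def _smoothstep(x: float) -> float:
    x = min(max(x, 0.0), 1.0)
    return x * x * (3 - 2 * x)


def _dotted_scenario(positions: Sequence[np.ndarray], dwell: float,
                     head_mode: str, rig: RigConfig, head_fraction: float,
                     ramp_s: float, sample_rate: float, kind: str) -> Scenario:
    positions = [np.asarray(p, dtype=float) for p in positions]
    n = len(positions)
    schedule = [(i, i * dwell, (i + 1) * dwell, tuple(positions[i]))
                for i in range(n)]

    def target(t: float) -> np.ndarray:
        k = min(int(t // dwell), n - 1)
        return positions[k]

    if head_mode == "fixed":
        def head(t: float) -> HeadPose:
            return HeadPose()
    elif head_mode == "toward_target":
        angles = [_head_angles_toward(p, rig, head_fraction) for p in positions]

        def head(t: float) -> HeadPose:
            k = min(int(t // dwell), n - 1)
            yaw1, pitch1 = angles[k]
            local = t - k * dwell
            if ramp_s <= 0 or local >= ramp_s:
                return HeadPose(yaw=yaw1, pitch=pitch1)
            yaw0, pitch0 = angles[k - 1] if k > 0 else (0.0, 0.0)
            w = _smoothstep(local / ramp_s)
            return HeadPose(yaw=yaw0 + w * (yaw1 - yaw0),
                            pitch=pitch0 + w * (pitch1 - pitch0))
    else:
        raise ValueError(f"head_mode must be 'fixed' or 'toward_target': {head_mode!r}")

    return Scenario(target_px=target, head_pose=head, duration_s=n * dwell,
                    sample_rate_hz=sample_rate, kind=kind, schedule=schedule)


def make_fixation_scenario(
    screen: ScreenGeometry = DEFAULT_SCREEN,
    n_cols: int = 4,
    n_rows: int = 4,
    dwell_s: float = 3.0,
    head_mode: str = "fixed",
    rig: RigConfig | None = None,
    head_fraction: float = 0.5,
    ramp_s: float = 0.3,
    sample_rate_hz: float = 30.0,
) -> Scenario:
    """Row-major grid of fixation dots (default 16 dots, 3 s each).

    ``head_mode="toward_target"`` rotates the head partway (``head_fraction``)
    toward each dot, clipped to +-18 deg yaw and +-10 deg pitch, with a short
    smooth ramp at each dot change.
    """
    rig = rig or RigConfig(screen=screen)
    xs = [(j + 0.5) * screen.res_x / n_cols for j in range(n_cols)]
    ys = [(i + 0.5) * screen.res_y / n_rows for i in range(n_rows)]
    positions = [np.array([x, y]) for y in ys for x in xs]
    return _dotted_scenario(positions, dwell_s, head_mode, rig, head_fraction,
                            ramp_s, sample_rate_hz, kind="fixation")


def make_calibration_scenario(
    screen: ScreenGeometry = DEFAULT_SCREEN,
    dots: Sequence[CalibrationDot] | None = None,
    dwell_s: float = 2.0,
    sample_rate_hz: float = 30.0,
) -> Scenario:
    """Five-dot calibration schedule with a fixed, neutral head."""
    dots = dots or default_calibration_dots(screen)
    rig = RigConfig(screen=screen)
    return _dotted_scenario([d.screen_position for d in dots], dwell_s, "fixed",
                            rig, 0.0, 0.0, sample_rate_hz, kind="calibration")


def make_pursuit_scenario(
    kind: str,
    screen: ScreenGeometry = DEFAULT_SCREEN,
    speed_px_s: float = 120.0,
    omega_deg_s: float = 15.0,
    radius_px: float = 350.0,
    rect_size_px: tuple[float, float] = (1200.0, 600.0),
    head_mode: str = "fixed",
    rig: RigConfig | None = None,
    head_fraction: float = 0.5,
    sample_rate_hz: float = 30.0,
) -> Scenario:
    """Smooth-pursuit target trajectories.

    * ``rect`` — clockwise perimeter traversal at 120 px/s starting from the
      upper-left vertex of a centred rectangle.
    * ``circle`` — clockwise sweep at 15 deg/s on a 350 px radius circle
      centred on the screen, starting at the top; duration one full lap.
    """
    rig = rig or RigConfig(screen=screen)
    cx, cy = screen.center_px
    if kind == "rect":
        w, h = rect_size_px
        x0, y0 = cx - w / 2, cy - h / 2
        if x0 < 0 or y0 < 0 or x0 + w > screen.res_x or y0 + h > screen.res_y:
            raise ValueError("rectangle exceeds screen bounds")
        perimeter = 2 * (w + h)
        duration = perimeter / speed_px_s

        def target(t: float) -> np.ndarray:
            sdist = (t * speed_px_s) % perimeter
            if sdist < w:
                return np.array([x0 + sdist, y0])
            sdist -= w
            if sdist < h:
                return np.array([x0 + w, y0 + sdist])
            sdist -= h
            if sdist < w:
                return np.array([x0 + w - sdist, y0 + h])
            sdist -= w
            return np.array([x0, y0 + h - sdist])
    elif kind == "circle":
        if radius_px > min(cx, cy):
            raise ValueError("circle exceeds screen bounds")
        duration = 360.0 / omega_deg_s

        def target(t: float) -> np.ndarray:
            a = np.radians(omega_deg_s * t)
            return np.array([cx + radius_px * np.sin(a),
                             cy - radius_px * np.cos(a)])
    else:
        raise ValueError(f"pursuit kind must be 'rect' or 'circle': {kind!r}")

    if head_mode == "fixed":
        def head(t: float) -> HeadPose:
            return HeadPose()
    elif head_mode == "toward_target":
        def head(t: float) -> HeadPose:
            yaw, pitch = _head_angles_toward(target(t), rig, head_fraction)
            return HeadPose(yaw=yaw, pitch=pitch)
    else:
        raise ValueError(f"head_mode must be 'fixed' or 'toward_target': {head_mode!r}")

    return Scenario(target_px=target, head_pose=head, duration_s=duration,
                    sample_rate_hz=sample_rate_hz, kind=f"pursuit_{kind}")


# --------------------------------------------------------------------------
# closed loop
# --------------------------------------------------------------------------


@dataclass
class ClosedLoopResult:
    calibration: CalibrationResult
    samples: list[GazeSample]
    truth_targets: np.ndarray
    truth_poses: list[HeadPose]
    target_ids: np.ndarray
    report: dict


def run_closed_loop(
    scenario: Scenario,
    rig: RigConfig | None = None,
    tracker_config: TrackerConfig | None = None,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    calibration_dwell_s: float = 2.0,
) -> ClosedLoopResult:
    """Calibrate on a rendered 5-dot stream (fixed head), then track the
    scenario stream and score predictions against the rig's ground truth."""
    rig = rig or RigConfig()
    seeds = np.random.SeedSequence(seed).generate_state(2)
    cal_scenario = make_calibration_scenario(
        rig.screen, dwell_s=calibration_dwell_s,
        sample_rate_hz=scenario.sample_rate_hz)
    cal_stream = ScenarioStream(cal_scenario, rig, noise_sigma_px,
                                seed=int(seeds[0]))
    calibration = run_calibration(
        cal_stream.frames(), default_calibration_dots(rig.screen), rig.screen,
        rig.intrinsics, dwell=calibration_dwell_s)

    stream = ScenarioStream(scenario, rig, noise_sigma_px, seed=int(seeds[1]))
    truth_targets, truth_poses, target_ids = stream.truth()
    state = TrackerState.from_calibration(calibration, tracker_config)
    samples = []
    for frame in stream.frames():
        sample, state = step(frame, state, rig.intrinsics, rig.screen,
                             rig.face_model)
        samples.append(sample)
    report = accuracy_report(samples, truth_targets, rig.screen,
                             target_ids=target_ids)
    return ClosedLoopResult(calibration, samples, truth_targets, truth_poses,
                            target_ids, report)
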