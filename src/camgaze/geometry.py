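"""Camera and screen geometry.

Conventions used throughout the package:

* Image and screen coordinates are top-left origin, x right, y down, 0-based,
  in (sub-)pixels.  Physical quantities are in millimetres.
* Head pose angles are in degrees.  Yaw is positive when the head turns toward
  the viewer's right on the screen (+x); pitch is positive when the head tilts
  upward (-y on screen); roll is about the rear-pointing optical axis,
  positive when the head's +x axis rotates toward +y (image-clockwise).
* The head-to-camera rotation is factored as
  ``R = Ry(-yaw) @ Rx(-pitch) @ Rz(roll)`` (angles in radians), so a neutral,
  screen-facing head has the identity rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .errors import CameraCalibrationError, GeometryError

__all__ = [
    "CameraIntrinsics",
    "ScreenGeometry",
    "HeadPose",
    "Checkerboard",
    "PnPResult",
    "CameraCalibrationResult",
    "euler_to_matrix",
    "matrix_to_euler",
    "project_points",
    "solve_pnp",
    "estimate_head_pose",
    "calibrate_camera",
    "checkerboard_object_points",
    "read_corner_csv",
    "px_to_mm",
    "mm_to_px",
    "visual_angle_error",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera intrinsics with a 5-coefficient distortion model.

    ``distortion`` holds ``(k1, k2, p1, p2, k3)``: radial terms k1..k3 and
    tangential terms p1, p2, all dimensionless.
    """

    focal_x: float
    focal_y: float
    principal_x: float
    principal_y: float
    image_width: int
    image_height: int
    distortion: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (self.focal_x > 0 and self.focal_y > 0):
            raise GeometryError("focal lengths must be positive")
        if not (self.image_width > 0 and self.image_height > 0):
            raise GeometryError("image size must be positive")
        if not (0 <= self.principal_x <= self.image_width
                and 0 <= self.principal_y <= self.image_height):
            raise GeometryError("principal point must lie within the image")
        if len(self.distortion) != 5:
            raise GeometryError("distortion must have 5 coefficients (k1,k2,p1,p2,k3)")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 camera matrix K."""
        return np.array(
            [
                [self.focal_x, 0.0, self.principal_x],
                [0.0, self.focal_y, self.principal_y],
                [0.0, 0.0, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "focal_x": float(self.focal_x),
            "focal_y": float(self.focal_y),
            "principal_x": float(self.principal_x),
            "principal_y": float(self.principal_y),
            "image_width": int(self.image_width),
            "image_height": int(self.image_height),
            "distortion": [float(v) for v in self.distortion],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        d = dict(d)
        d["distortion"] = tuple(d.get("distortion", (0.0,) * 5))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"camera": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CameraIntrinsics":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["camera"] if "camera" in data else data)


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen resolution, physical size and viewing distance ``d``."""

    res_x: int
    res_y: int
    width_mm: float
    height_mm: float
    viewing_distance_mm: float = 500.0

    def __post_init__(self):
        vals = (self.res_x, self.res_y, self.width_mm, self.height_mm,
                self.viewing_distance_mm)
        if any(v <= 0 for v in vals):
            raise GeometryError("all screen geometry fields must be positive")
        if not (0.05 <= self.width_mm / self.res_x <= 1.0):
            raise GeometryError("pixel pitch outside the sane range [0.05, 1.0] mm/px")

    @property
    def pitch_x(self) -> float:
        """mm per pixel along x."""
        return self.width_mm / self.res_x

    @property
    def pitch_y(self) -> float:
        """mm per pixel along y."""
        return self.height_mm / self.res_y

    @property
    def center_px(self) -> np.ndarray:
        return np.array([self.res_x / 2.0, self.res_y / 2.0])

    def to_dict(self) -> dict:
        return {
            "res_x": int(self.res_x),
            "res_y": int(self.res_y),
            "width_mm": float(self.width_mm),
            "height_mm": float(self.height_mm),
            "viewing_distance_mm": float(self.viewing_distance_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"screen": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScreenGeometry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["screen"] if "screen" in data else data)


@dataclass(frozen=True)
class HeadPose:
    """Head orientation in degrees; ``valid`` is False when estimation failed."""

    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0
    valid: bool = True
    reprojection_rms_px: float = 0.0

    def __post_init__(self):
        if self.valid:
            for a in (self.pitch, self.yaw, self.roll):
                if not (-90.0 < a < 90.0):
                    raise GeometryError(f"valid pose angle out of (-90, 90): {a}")

    @classmethod
    def invalid(cls) -> "HeadPose":
        return cls(0.0, 0.0, 0.0, valid=False)


@dataclass(frozen=True)
class Checkerboard:
    """Inner-corner grid of a physical checkerboard."""

    rows: int
    cols: int
    square_mm: float

    @property
    def n_corners(self) -> int:
        return self.rows * self.cols


# --------------------------------------------------------------------------
# rotations and projection
# --------------------------------------------------------------------------


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_to_matrix(yaw: float, pitch: float, roll: float = 0.0,
                    degrees: bool = True) -> np.ndarray:
    """Head-to-camera rotation matrix for the package's angle convention."""
    if degrees:
        yaw, pitch, roll = np.radians([yaw, pitch, roll])
    return _ry(-yaw) @ _rx(-pitch) @ _rz(roll)


def matrix_to_euler(R: np.ndarray, degrees: bool = True) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; returns ``(yaw, pitch, roll)``."""
    pitch = np.arcsin(np.clip(R[1, 2], -1.0, 1.0))
    yaw = np.arctan2(-R[0, 2], R[2, 2])
    roll = np.arctan2(R[1, 0], R[1, 1])
    if degrees:
        yaw, pitch, roll = np.degrees([yaw, pitch, roll])
    return float(yaw), float(pitch), float(roll)


def project_points(points_cam: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame 3D points (N,3) to image pixels (N,2).

    Applies the 5-coefficient radial/tangential distortion model.
    Points must have positive depth (z > 0).
    """
    p = np.asarray(points_cam, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    z = p[:, 2]
    if np.any(z <= 0):
        raise GeometryError("cannot project points at or behind the camera plane")
    x = p[:, 0] / z
    y = p[:, 1] / z
    k1, k2, p1, p2, k3 = intrinsics.distortion
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    uv = np.column_stack(
        [
            intrinsics.focal_x * xd + intrinsics.principal_x,
            intrinsics.focal_y * yd + intrinsics.principal_y,
        ]
    )
    return uv[0] if single else uv


# --------------------------------------------------------------------------
# perspective-n-point head pose
# --------------------------------------------------------------------------


@dataclass
class PnPResult:
    rotation: np.ndarray            # 3x3, model->camera
    translation: np.ndarray         # (3,), mm
    reprojection_rms_px: float
    success: bool


def _rotvec_to_matrix(rv: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rv)
    if theta < 1e-12:
        return np.eye(3)
    k = rv / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    cos_t = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_t)
    if theta < 1e-12:
        return np.zeros(3)
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(axis)
    if n < 1e-12:  # theta ~ pi
        # fall back to eigen-decomposition
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
        return axis / np.linalg.norm(axis) * theta
    return axis / n * theta


def _points_collinear(points2d: np.ndarray, tol: float = 1e-8) -> bool:
    q = points2d - points2d.mean(axis=0)
    s = np.linalg.svd(q, compute_uv=False)
    return s[0] < tol or s[1] / s[0] < tol


def solve_pnp(
    model_points: np.ndarray,
    image_points: np.ndarray,
    intrinsics: CameraIntrinsics,
    initial: PnPResult | None = None,
) -> PnPResult:
    """Recover the rigid model-to-camera pose from n>=4 2D-3D correspondences.

    Levenberg-Marquardt minimisation of the reprojection error over a
    rotation-vector + translation parameterisation.  ``initial`` warm-starts
    the solver (useful when tracking, where poses change slowly).
    """
    model = np.asarray(model_points, dtype=float)
    img = np.asarray(image_points, dtype=float)
    if model.shape[0] != img.shape[0] or model.shape[0] < 4:
        raise GeometryError("need at least 4 matching model/image points")
    if _points_collinear(img):
        return PnPResult(np.eye(3), np.zeros(3), np.inf, success=False)

    if initial is not None and initial.success:
        x0 = np.concatenate([_matrix_to_rotvec(initial.rotation), initial.translation])
    else:
        # depth guess from the ratio of metric to pixel spread
        spread_model = np.linalg.norm(model - model.mean(axis=0), axis=1).mean()
        spread_img = np.linalg.norm(img - img.mean(axis=0), axis=1).mean()
        f = 0.5 * (intrinsics.focal_x + intrinsics.focal_y)
        z0 = f * spread_model / max(spread_img, 1e-6)
        cx, cy = intrinsics.principal_x, intrinsics.principal_y
        t0 = np.array(
            [
                (img[:, 0].mean() - cx) / intrinsics.focal_x * z0,
                (img[:, 1].mean() - cy) / intrinsics.focal_y * z0,
                z0,
            ]
        ) - model.mean(axis=0)
        x0 = np.concatenate([np.zeros(3), t0])

    def residuals(x):
        R = _rotvec_to_matrix(x[:3])
        cam = model @ R.T + x[3:]
        if np.any(cam[:, 2] <= 1e-6):
            return np.full(2 * len(model), 1e6)
        return (project_points(cam, intrinsics) - img).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, max_nfev=400)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    R = _rotvec_to_matrix(sol.x[:3])
    return PnPResult(R, sol.x[3:].copy(), rms, success=np.isfinite(rms))


def estimate_head_pose(
    image_points: np.ndarray,
    model_points: np.ndarray,
    intrinsics: CameraIntrinsics,
    initial: PnPResult | None = None,
) -> tuple[HeadPose, PnPResult]:
    """Estimate pitch/yaw/roll from the six facial PnP correspondences.

    Returns ``(pose, pnp_result)``; a degenerate (collinear) configuration
    yields ``pose.valid == False``.
    """
    image_points = np.asarray(image_points, dtype=float)
    model_points = np.asarray(model_points, dtype=float)
    if image_points.shape != (6, 2) or model_points.shape != (6, 3):
        raise GeometryError("head pose estimation expects exactly six 2D/3D points")
    res = solve_pnp(model_points, image_points, intrinsics, initial=initial)
    if not res.success:
        return HeadPose.invalid(), res
    yaw, pitch, roll = matrix_to_euler(res.rotation)
    if any(not (-90.0 < a < 90.0) for a in (yaw, pitch, roll)):
        return HeadPose.invalid(), res
    return HeadPose(pitch=pitch, yaw=yaw, roll=roll,
                    reprojection_rms_px=res.reprojection_rms_px), res


# --------------------------------------------------------------------------
# checkerboard camera calibration (Zhang's method)
# --------------------------------------------------------------------------


def checkerboard_object_points(board: Checkerboard) -> np.ndarray:
    """Planar (N,3) object points of the board's inner corners, z = 0, row-major."""
    jj, ii = np.meshgrid(np.arange(board.cols), np.arange(board.rows))
    return np.column_stack(
        [jj.ravel() * board.square_mm, ii.ravel() * board.square_mm,
         np.zeros(board.n_corners)]
    )


def _homography_dlt(obj_xy: np.ndarray, img: np.ndarray) -> np.ndarray:
    def normalise(pts):
        mean = pts.mean(axis=0)
        scale = np.sqrt(2) / max(np.linalg.norm(pts - mean, axis=1).mean(), 1e-12)
        T = np.array([[scale, 0, -scale * mean[0]],
                      [0, scale, -scale * mean[1]],
                      [0, 0, 1]])
        pn = (pts - mean) * scale
        return pn, T

    pn, Tp = normalise(obj_xy)
    qn, Tq = normalise(img)
    n = len(pn)
    A = np.zeros((2 * n, 9))
    for i in range(n):
        X, Y = pn[i]
        u, v = qn[i]
        A[2 * i] = [-X, -Y, -1, 0, 0, 0, u * X, u * Y, u]
        A[2 * i + 1] = [0, 0, 0, -X, -Y, -1, v * X, v * Y, v]
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tq) @ H @ Tp
    return H / H[2, 2]


def _vij(H, i, j):
    return np.array(
        [
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ]
    )


@dataclass
class CameraCalibrationResult:
    intrinsics: CameraIntrinsics
    rms_px: float
    per_view_rms_px: list[float] = field(default_factory=list)


def calibrate_camera(
    corner_views: Sequence[np.ndarray],
    board: Checkerboard,
    image_size: tuple[int, int],
) -> CameraCalibrationResult:
    """Zhang planar calibration from >=3 checkerboard corner views.

    ``corner_views`` holds one (rows*cols, 2) pixel array per view, corners in
    row-major board order.  Raises :class:`CameraCalibrationError` on too few
    views, inconsistent grids, or a rank-deficient (e.g. duplicated-view)
    configuration.
    """
    if len(corner_views) < 3:
        raise CameraCalibrationError(f"need at least 3 views, got {len(corner_views)}")
    obj = checkerboard_object_points(board)
    views = []
    for i, v in enumerate(corner_views):
        v = np.asarray(v, dtype=float)
        if v.shape != (board.n_corners, 2):
            raise CameraCalibrationError(
                f"view {i}: expected {board.n_corners} corners, got {v.shape}")
        views.append(v)

    homographies = [_homography_dlt(obj[:, :2], v) for v in views]
    V = np.vstack([
        row for H in homographies
        for row in (_vij(H, 0, 1), _vij(H, 0, 0) - _vij(H, 1, 1))
    ])
    s = np.linalg.svd(V, compute_uv=False)
    # one small singular value is the solution direction; two near-zero ones
    # mean the views do not constrain the conic (e.g. duplicated views)
    if s[-2] / s[0] < 1e-8:
        raise CameraCalibrationError("ill-conditioned view set (views too similar)")
    _, _, vt = np.linalg.svd(V)
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12**2
    try:
        v0 = (b12 * b13 - b11 * b23) / denom
        lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
        fx = np.sqrt(lam / b11)
        fy = np.sqrt(lam * b11 / denom)
        u0 = -b13 * fx**2 / lam
    except (ZeroDivisionError, FloatingPointError):
        raise CameraCalibrationError("degenerate closed-form solution")
    if not np.isfinite([fx, fy, u0, v0]).all() or fx <= 0 or fy <= 0:
        raise CameraCalibrationError("closed-form intrinsics are not physical")

    K = np.array([[fx, 0, u0], [0, fy, v0], [0, 0, 1]])
    Kinv = np.linalg.inv(K)
    extr = []
    for H in homographies:
        h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
        lam_e = 1.0 / np.linalg.norm(Kinv @ h1)
        r1 = lam_e * (Kinv @ h1)
        r2 = lam_e * (Kinv @ h2)
        t = lam_e * (Kinv @ h3)
        r3 = np.cross(r1, r2)
        Q = np.column_stack([r1, r2, r3])
        u_, _, vt_ = np.linalg.svd(Q)
        R = u_ @ vt_
        if t[2] < 0:
            R, t = -R, -t  # board behind camera: flip
        extr.append(np.concatenate([_matrix_to_rotvec(R), t]))

    n_views = len(views)
    x0 = np.concatenate([[fx, fy, u0, v0, 0, 0, 0, 0, 0], np.concatenate(extr)])
    all_img = np.vstack(views)

    def residuals(x):
        intr = CameraIntrinsics(
            focal_x=abs(x[0]), focal_y=abs(x[1]),
            principal_x=np.clip(x[2], 0, image_size[0]),
            principal_y=np.clip(x[3], 0, image_size[1]),
            image_width=image_size[0], image_height=image_size[1],
            distortion=tuple(x[4:9]),
        )
        proj = []
        for k in range(n_views):
            p = x[9 + 6 * k: 15 + 6 * k]
            R = _rotvec_to_matrix(p[:3])
            cam = obj @ R.T + p[3:]
            if np.any(cam[:, 2] <= 1e-6):
                return np.full(all_img.size, 1e6)
            proj.append(project_points(cam, intr))
        return (np.vstack(proj) - all_img).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        max_nfev=300)
    res = sol.fun.reshape(-1, 2)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    per_view = [
        float(np.sqrt(np.mean(np.sum(
            res[k * board.n_corners:(k + 1) * board.n_corners]**2, axis=1))))
        for k in range(n_views)
    ]
    intr = CameraIntrinsics(
        focal_x=abs(sol.x[0]), focal_y=abs(sol.x[1]),
        principal_x=float(np.clip(sol.x[2], 0, image_size[0])),
        principal_y=float(np.clip(sol.x[3], 0, image_size[1])),
        image_width=image_size[0], image_height=image_size[1],
        distortion=tuple(float(v) for v in sol.x[4:9]),
    )
    return CameraCalibrationResult(intr, rms, per_view)


def read_corner_csv(path) -> dict[int, np.ndarray]:
    """Read checkerboard corners from CSV (view_id, corner_row, corner_col, x_px, y_px).

    Returns ``{view_id: (rows*cols, 2) array}`` with corners in row-major order.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"view_id", "corner_row", "corner_col", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise CameraCalibrationError(f"corner CSV must have columns {sorted(required)}")
    out = {}
    for vid, g in df.groupby("view_id"):
        g = g.sort_values(["corner_row", "corner_col"])
        out[int(vid)] = g[["x_px", "y_px"]].to_numpy(dtype=float)
    return out


# --------------------------------------------------------------------------
# unit conversions and the visual-angle metric
# --------------------------------------------------------------------------


def px_to_mm(point_px, screen: ScreenGeometry) -> np.ndarray:
    """Screen pixels -> millimetres (same top-left origin)."""
    p = np.asarray(point_px, dtype=float)
    return p * np.array([screen.pitch_x, screen.pitch_y])


def mm_to_px(point_mm, screen: ScreenGeometry) -> np.ndarray:
    """Millimetres -> screen pixels; exact inverse of :func:`px_to_mm`."""
    p = np.asarray(point_mm, dtype=float)
    return p / np.array([screen.pitch_x, screen.pitch_y])


def visual_angle_error(pred_px, truth_px, screen: ScreenGeometry,
                       axis: str | None = None):
    """Angular separation (degrees) between predicted and true gaze points.

    ``atan(separation_mm / viewing_distance_mm)``; ``axis`` of ``"x"``/``"y"``
    uses the per-axis separation only.  Accepts single points or (N,2) arrays.
    """
    if screen.viewing_distance_mm <= 0:
        raise GeometryError("viewing distance must be positive")
    dp = px_to_mm(pred_px, screen) - px_to_mm(truth_px, screen)
    dp = np.atleast_2d(dp)
    if axis == "x":
        sep = np.abs(dp[:, 0])
    elif axis == "y":
        sep = np.abs(dp[:, 1])
    elif axis is None:
        sep = np.linalg.norm(dp, axis=1)
    else:
        raise ValueError(f"axis must be None, 'x' or 'y', got {axis!r}")
    ang = np.degrees(np.arctan(sep / screen.viewing_distance_mm))
    return float(ang[0]) if ang.size == 1 and np.asarray(pred_px).ndim == 1 else ang
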