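"""Landmark-backend contract and per-frame eye-feature extraction.

The tracker consumes frames of 2D facial landmarks in the face-mesh index
space (468 face points + 10 iris points).  Only fourteen indices are actually
used; they are fixed in :data:`LANDMARK_INDICES`.  ``left``/``right`` always
refer to *image* space (the user's right eye appears on the image left in an
unmirrored webcam frame).

Frames come from a pluggable backend: a replay of a recorded CSV log, the
synthetic rig in :mod:`camgaze.simulator`, or (out of core scope) a live
neural-network detector satisfying the same protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol, runtime_checkable

import numpy as np

from .errors import FeatureExtractionError, StreamError

__all__ = [
    "LANDMARK_INDICES",
    "PNP_LANDMARK_IDS",
    "FACE_MODEL_POINTS",
    "LandmarkFrame",
    "EyeFeatures",
    "extract_eye_features",
    "landmark_stream",
    "write_landmark_log",
    "read_landmark_log",
    "LandmarkSource",
]

#: Face-mesh landmark indices consumed by the tracker.  Iris-center indices
#: follow the refined-landmark numbering (468..472 image-left iris with 468
#: the center, 473..477 image-right iris with 473 the center).  The pupil
#: center is taken to be the iris-center landmark, not the centroid of the
#: 4-point iris ring (configurable alternative documented in docs/methods.md).
LANDMARK_INDICES = {
    "nose_tip": 1,
    "chin": 152,
    "left_eye_outer": 33,
    "left_eye_inner": 133,
    "right_eye_inner": 362,
    "right_eye_outer": 263,
    "left_mouth": 61,
    "right_mouth": 291,
    "left_iris_center": 468,
    "right_iris_center": 473,
}

#: The six landmarks used for perspective-n-point head pose, in the order
#: matching :data:`FACE_MODEL_POINTS`.
PNP_LANDMARK_IDS = (
    LANDMARK_INDICES["nose_tip"],
    LANDMARK_INDICES["chin"],
    LANDMARK_INDICES["left_eye_outer"],
    LANDMARK_INDICES["right_eye_outer"],
    LANDMARK_INDICES["left_mouth"],
    LANDMARK_INDICES["right_mouth"],
)

#: Generic rigid 3D face model for pose estimation, in head-local mm:
#: nose tip at the origin, x toward image right, y down, z toward the back of
#: the head.  Row order matches :data:`PNP_LANDMARK_IDS`.  The model is
#: stylised: the eye-corner points are placed in the corneal plane (z = 3 mm,
#: the depth of a screen-directed pupil) so that these near-pupil surface
#: points displace like the pupil itself under rigid head motion — the
#: geometric assumption behind the eye-corner benchmark update.
FACE_MODEL_POINTS = np.array(
    [
        [0.0, 0.0, 0.0],      # nose tip
        [0.0, 65.0, 15.0],    # chin
        [-45.0, -35.0, 3.0],   # image-left outer eye corner
        [45.0, -35.0, 3.0],    # image-right outer eye corner
        [-26.0, 28.0, 20.0],   # image-left mouth corner
        [26.0, 28.0, 20.0],    # image-right mouth corner
    ]
)


@dataclass
class LandmarkFrame:
    """One timestamped set of 2D landmarks in image pixels."""

    timestamp: float
    points: dict[int, np.ndarray]
    image_width: int
    image_height: int
    source: str = "replay"

    def get(self, index: int) -> np.ndarray:
        try:
            return self.points[index]
        except KeyError:
            raise FeatureExtractionError(index) from None


@dataclass
class EyeFeatures:
    """Pupil centers and eye corners for one frame, plus the PnP points."""

    pupil_left: np.ndarray
    pupil_right: np.ndarray
    inner_corner_left: np.ndarray
    outer_corner_left: np.ndarray
    inner_corner_right: np.ndarray
    outer_corner_right: np.ndarray
    pnp_points: np.ndarray  # (6, 2)

    def corners(self) -> np.ndarray:
        """(4, 2) array: inner-left, outer-left, inner-right, outer-right."""
        return np.array(
            [
                self.inner_corner_left,
                self.outer_corner_left,
                self.inner_corner_right,
                self.outer_corner_right,
            ]
        )


def extract_eye_features(frame: LandmarkFrame) -> EyeFeatures:
    """Pure landmark indexing; raises naming the first missing index."""
    idx = LANDMARK_INDICES
    pnp = np.array([frame.get(i) for i in PNP_LANDMARK_IDS], dtype=float)
    return EyeFeatures(
        pupil_left=np.asarray(frame.get(idx["left_iris_center"]), dtype=float),
        pupil_right=np.asarray(frame.get(idx["right_iris_center"]), dtype=float),
        inner_corner_left=np.asarray(frame.get(idx["left_eye_inner"]), dtype=float),
        outer_corner_left=np.asarray(frame.get(idx["left_eye_outer"]), dtype=float),
        inner_corner_right=np.asarray(frame.get(idx["right_eye_inner"]), dtype=float),
        outer_corner_right=np.asarray(frame.get(idx["right_eye_outer"]), dtype=float),
        pnp_points=pnp,
    )


# --------------------------------------------------------------------------
# landmark log I/O
# --------------------------------------------------------------------------


def write_landmark_log(frames: Iterable[LandmarkFrame], csv_path,
                       sidecar: dict | None = None) -> None:
    """Write a landmark log: CSV (timestamp_s, landmark_id, x_px, y_px) plus a
    JSON sidecar (image size, source, optional seed).

    Floats are written with ``repr`` so a read-back stream is bit-identical.
    """
    csv_path = Path(csv_path)
    meta = dict(sidecar or {})
    n = 0
    with open(csv_path, "w") as fh:
        fh.write("timestamp_s,landmark_id,x_px,y_px\n")
        for frame in frames:
            n += 1
            meta.setdefault("image_width", frame.image_width)
            meta.setdefault("image_height", frame.image_height)
            meta.setdefault("source", frame.source)
            for lid in sorted(frame.points):
                x, y = frame.points[lid]
                fh.write(f"{float(frame.timestamp)!r},{lid},{float(x)!r},{float(y)!r}\n")
    meta["n_frames"] = n
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_landmark_log(csv_path) -> Iterator[LandmarkFrame]:
    """Replay a landmark log, yielding frames grouped by timestamp.

    Raises :class:`StreamError` at the first timestamp inversion.
    """
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        meta = {}
    width = int(meta.get("image_width", 0))
    height = int(meta.get("image_height", 0))
    source = meta.get("source", "replay")

    current_t: float | None = None
    points: dict[int, np.ndarray] = {}
    with open(csv_path) as fh:
        header = fh.readline().strip().split(",")
        if header[:4] != ["timestamp_s", "landmark_id", "x_px", "y_px"]:
            raise StreamError(f"unexpected landmark log header: {header}")
        for lineno, line in enumerate(fh, start=2):
            ts, lid, x, y = line.rstrip("\n").split(",")
            t = float(ts)
            if current_t is not None and t != current_t:
                if t <= current_t:
                    raise StreamError(
                        f"non-monotonic timestamp {t} at line {lineno} of {csv_path}")
                yield LandmarkFrame(current_t, points, width, height, source)
                points = {}
            current_t = t
            points[int(lid)] = np.array([float(x), float(y)])
    if current_t is not None:
        yield LandmarkFrame(current_t, points, width, height, source)


# --------------------------------------------------------------------------
# backend protocol and stream construction
# --------------------------------------------------------------------------


@runtime_checkable
class LandmarkSource(Protocol):
    """Anything that can produce a landmark stream (simulator, live detector)."""

    def frames(self) -> Iterator[LandmarkFrame]: ...


def landmark_stream(backend) -> Iterator[LandmarkFrame]:
    """Build a validated frame iterator from a backend specification.

    Accepted backends: a path to a recorded CSV log (replay), any
    :class:`LandmarkSource` (e.g. the synthetic rig stream), or a plain
    iterable of :class:`LandmarkFrame`.  Timestamps must be strictly
    increasing; a violation raises :class:`StreamError` at the offending
    frame.
    """
    if isinstance(backend, (str, Path)):
        inner = read_landmark_log(backend)
    elif isinstance(backend, LandmarkSource):
        inner = backend.frames()
    elif isinstance(backend, Iterable):
        inner = iter(backend)
    else:
        raise StreamError(f"unknown landmark backend: {backend!r}")

    def checked() -> Iterator[LandmarkFrame]:
        last = -np.inf
        for frame in inner:
            if frame.timestamp <= last:
                raise StreamError(
                    f"non-monotonic timestamp {frame.timestamp} (previous {last})")
            last = frame.timestamp
            yield frame

    return checked()
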