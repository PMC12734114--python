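"""Eye-movement analytics and accuracy scoring.

* I-VT classification: a sample is a saccade when the point-to-point angular
  velocity exceeds a threshold (default 30 deg/s), a fixation otherwise;
  fixation runs shorter than a minimum duration (default 60 ms) are dropped.
* Gaze heatmaps: a sum of isotropic Gaussian kernels (truncated at 3 sigma)
  over all valid gaze points, normalised to unit mass.
* Accuracy reports: per-target / per-region / overall visual-angle errors and
  per-axis RMSE in pixels, with regions the four equal screen quadrants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import MetricsError
from .geometry import ScreenGeometry, visual_angle_error
from .tracker import GazeSample

__all__ = [
    "FixationEvent",
    "HeatmapGrid",
    "IVTConfig",
    "ivt_classify",
    "fixation_count",
    "fixation_stats",
    "build_heatmap",
    "render_heatmap_png",
    "accuracy_report",
    "write_fixation_events",
]


@dataclass(frozen=True)
class IVTConfig:
    velocity_threshold_deg_s: float = 30.0
    min_fixation_s: float = 0.06
    gap_factor: float = 3.0   # dt > gap_factor * nominal frame interval breaks a run


@dataclass
class FixationEvent:
    start_s: float
    end_s: float
    centroid: np.ndarray
    n_samples: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class HeatmapGrid:
    """Non-negative attention grid; ``cell_px`` pixels per cell per axis."""

    values: np.ndarray
    cell_px: int = 1
    normalized: bool = True

    def save_txt(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.8e",
                   header=f"cell_px={self.cell_px} normalized={self.normalized}")


# --------------------------------------------------------------------------
# I-VT
# --------------------------------------------------------------------------


def _segments(samples: Sequence[GazeSample], gap_factor: float) -> list[list[int]]:
    """Indices of valid samples grouped into runs with no timestamp gaps."""
    valid_idx = [i for i, s in enumerate(samples) if s.valid]
    if len(valid_idx) < 2:
        return [valid_idx] if valid_idx else []
    dts = np.diff([samples[i].timestamp for i in valid_idx])
    nominal = float(np.median(dts))
    segments, cur = [], [valid_idx[0]]
    for k, i in enumerate(valid_idx[1:]):
        # an invalid sample between two valid ones also breaks the run
        contiguous = i == cur[-1] + 1
        if dts[k] > gap_factor * nominal or not contiguous:
            segments.append(cur)
            cur = [i]
        else:
            cur.append(i)
    segments.append(cur)
    return segments


def ivt_classify(
    samples: Sequence[GazeSample],
    screen: ScreenGeometry,
    config: IVTConfig | None = None,
) -> tuple[list[str], list[FixationEvent]]:
    """Velocity-threshold classification of a gaze-sample sequence.

    Returns per-sample labels (``"fixation"`` / ``"saccade"`` / ``"invalid"``)
    and the list of surviving fixation events.  Velocities are computed only
    between consecutive valid samples inside a run (no velocity across
    invalid samples or timestamp gaps); the first sample of a run inherits
    the label of its successor.
    """
    config = config or IVTConfig()
    labels = ["invalid"] * len(samples)
    events: list[FixationEvent] = []
    for seg in _segments(samples, config.gap_factor):
        if len(seg) == 1:
            labels[seg[0]] = "fixation"
            continue
        seg_labels = [None] * len(seg)
        for k in range(1, len(seg)):
            a, b = samples[seg[k - 1]], samples[seg[k]]
            dt = b.timestamp - a.timestamp
            vel = visual_angle_error(b.gaze, a.gaze, screen) / dt
            seg_labels[k] = "saccade" if vel > config.velocity_threshold_deg_s \
                else "fixation"
        seg_labels[0] = seg_labels[1]
        for k, i in enumerate(seg):
            labels[i] = seg_labels[k]
        # fixation events: contiguous fixation runs inside this segment
        k = 0
        while k < len(seg):
            if seg_labels[k] == "fixation":
                j = k
                while j + 1 < len(seg) and seg_labels[j + 1] == "fixation":
                    j += 1
                run = seg[k:j + 1]
                start = samples[run[0]].timestamp
                end = samples[run[-1]].timestamp
                if end - start >= config.min_fixation_s:
                    centroid = np.mean([samples[i].gaze for i in run], axis=0)
                    events.append(FixationEvent(start, end, centroid, len(run)))
                k = j + 1
            else:
                k += 1
    return labels, events


def fixation_count(events: Sequence[FixationEvent]) -> int:
    return len(events)


def fixation_stats(events: Sequence[FixationEvent]) -> dict:
    """Count and mean duration of the fixation events."""
    return {
        "count": len(events),
        "mean_duration_s": float(np.mean([e.duration_s for e in events]))
        if events else 0.0,
    }


def write_fixation_events(events: Sequence[FixationEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s,end_s,centroid_x,centroid_y,n_samples\n")
        for e in events:
            fh.write(f"{float(e.start_s)!r},{float(e.end_s)!r},"
                     f"{float(e.centroid[0])!r},{float(e.centroid[1])!r},"
                     f"{e.n_samples}\n")


# --------------------------------------------------------------------------
# heatmaps
# --------------------------------------------------------------------------


def build_heatmap(
    samples: Sequence[GazeSample],
    screen: ScreenGeometry,
    sigma_px: float | None = None,
    grid_downsample: int = 1,
    normalize: bool = True,
) -> HeatmapGrid:
    """Sum of per-sample isotropic Gaussian kernels truncated at 3 sigma.

    ``sigma_px`` defaults to 2% of the screen width.  With ``normalize`` the
    grid sums to one.
    """
    points = [s.gaze for s in samples if s.valid and np.all(np.isfinite(s.gaze))]
    if not points:
        raise MetricsError("no valid gaze samples to build a heatmap from")
    if sigma_px is None:
        sigma_px = 0.02 * screen.res_x
    if sigma_px <= 0:
        raise MetricsError("sigma_px must be positive")
    ds = max(1, int(grid_downsample))
    ny, nx = screen.res_y // ds, screen.res_x // ds
    sigma = sigma_px / ds
    radius = int(np.ceil(3 * sigma))
    grid = np.zeros((ny, nx))
    win = np.arange(-radius, radius + 1)
    for p in points:
        cx, cy = p[0] / ds, p[1] / ds
        ix, iy = int(round(cx)), int(round(cy))
        xs, ys = win + ix, win + iy
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma**2))
        mx = (xs >= 0) & (xs < nx)
        my = (ys >= 0) & (ys < ny)
        if not mx.any() or not my.any():
            continue
        grid[np.ix_(ys[my], xs[mx])] += np.outer(gy[my], gx[mx])
    if normalize:
        total = grid.sum()
        if total <= 0:
            raise MetricsError("heatmap has zero mass (all points off-grid)")
        grid /= total
    return HeatmapGrid(values=grid, cell_px=ds, normalized=normalize)


def render_heatmap_png(grid: HeatmapGrid, path) -> None:
    """Render with the conventional blue->green->yellow->red attention ramp."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, grid.values, cmap="turbo", origin="upper")


# --------------------------------------------------------------------------
# accuracy reports
# --------------------------------------------------------------------------


def _region_of(point: np.ndarray, screen: ScreenGeometry) -> int:
    """Quadrant of the true target: 0 TL, 1 TR, 2 BL, 3 BR."""
    col = 1 if point[0] >= screen.res_x / 2 else 0
    row = 1 if point[1] >= screen.res_y / 2 else 0
    return row * 2 + col


def accuracy_report(
    samples: Sequence[GazeSample],
    truth_targets: np.ndarray,
    screen: ScreenGeometry,
    target_ids: Sequence[int] | None = None,
) -> dict:
    """Score predicted gaze against per-sample true target positions.

    ``truth_targets`` is (N,2) aligned with ``samples``; ``target_ids``
    optionally labels each sample with a target index for per-target means.
    Samples that are invalid or lack a finite truth are excluded.
    """
    truth = np.asarray(truth_targets, dtype=float)
    if len(truth) != len(samples):
        raise MetricsError("truth must align one-to-one with samples")
    keep = [i for i, s in enumerate(samples)
            if s.valid and np.all(np.isfinite(truth[i]))]
    if not keep:
        raise MetricsError("no overlap between valid samples and truth")
    pred = np.array([samples[i].gaze for i in keep])
    tru = truth[keep]
    ang = visual_angle_error(pred, tru, screen)
    ang_x = visual_angle_error(pred, tru, screen, axis="x")
    ang_y = visual_angle_error(pred, tru, screen, axis="y")
    resid = pred - tru
    report = {
        "overall": {
            "mean_error_deg": float(np.mean(ang)),
            "mean_error_x_deg": float(np.mean(ang_x)),
            "mean_error_y_deg": float(np.mean(ang_y)),
            "rmse_x_px": float(np.sqrt(np.mean(resid[:, 0] ** 2))),
            "rmse_y_px": float(np.sqrt(np.mean(resid[:, 1] ** 2))),
            "n_samples": len(keep),
        },
        "per_region": {},
        "per_target": {},
    }
    regions = np.array([_region_of(t, screen) for t in tru])
    for r in range(4):
        mask = regions == r
        if mask.any():
            report["per_region"][str(r)] = {
                "mean_error_deg": float(np.mean(ang[mask])),
                "n_samples": int(mask.sum()),
            }
    if target_ids is not None:
        ids = np.asarray(target_ids)[keep]
        for tid in np.unique(ids):
            if tid < 0:
                continue
            mask = ids == tid
            report["per_target"][str(int(tid))] = {
                "mean_error_deg": float(np.mean(ang[mask])),
                "target": [float(v) for v in tru[mask][0]],
                "n_samples": int(mask.sum()),
            }
    return report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
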