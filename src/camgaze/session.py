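"""End-to-end orchestration: config files, task runs, artifact bundles.

A session ties the modules together into the two evaluation tasks (fixation
grid, smooth pursuit) and the analytics use case: calibrate -> track ->
I-VT events + heatmap + accuracy report, with every artifact written to
disk so a run is reproducible from (config, seed | input log) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import (DEFAULT_EDGE_MARGIN_PX, CalibrationResult,
                          default_calibration_dots, run_calibration)
from .errors import CalibrationError, MetricsError
from .features import landmark_stream, write_landmark_log
from .geometry import CameraIntrinsics, ScreenGeometry
from .metrics import (IVTConfig, accuracy_report, build_heatmap, fixation_stats,
                      ivt_classify, render_heatmap_png, save_report,
                      write_fixation_events)
from .simulator import (DEFAULT_INTRINSICS, DEFAULT_SCREEN, RigConfig,
                        ScenarioStream, make_fixation_scenario,
                        make_pursuit_scenario, run_closed_loop)
from .tracker import TrackerConfig, track, write_gaze_log

logger = logging.getLogger("camgaze")

__all__ = ["SessionConfig", "run_task", "TASKS"]

TASKS = ("fixation", "pursuit_rect", "pursuit_circle")


@dataclass
class SessionConfig:
    """One-file configuration; defaults echo the evaluation setup
    (d = 500 mm, 1920x1080, 30 Hz, 2-degree threshold, 3 s dot dwell,
    120 px/s rectangle, 15 deg/s circle of 350 px radius)."""

    screen: ScreenGeometry = field(default_factory=lambda: DEFAULT_SCREEN)
    intrinsics: CameraIntrinsics = field(default_factory=lambda: DEFAULT_INTRINSICS)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    ivt: IVTConfig = field(default_factory=IVTConfig)
    calibration_margin_px: float = DEFAULT_EDGE_MARGIN_PX
    calibration_dwell_s: float = 2.0
    head_mode: str = "fixed"
    noise_sigma_px: float = 0.0
    seed: int = 0
    sample_rate_hz: float = 30.0
    heatmap_downsample: int = 4

    def to_dict(self) -> dict:
        return {
            "screen": self.screen.to_dict(),
            "camera": self.intrinsics.to_dict(),
            "tracker": self.tracker.to_dict(),
            "ivt": {
                "velocity_threshold_deg_s": self.ivt.velocity_threshold_deg_s,
                "min_fixation_s": self.ivt.min_fixation_s,
                "gap_factor": self.ivt.gap_factor,
            },
            "calibration_margin_px": self.calibration_margin_px,
            "calibration_dwell_s": self.calibration_dwell_s,
            "head_mode": self.head_mode,
            "noise_sigma_px": self.noise_sigma_px,
            "seed": self.seed,
            "sample_rate_hz": self.sample_rate_hz,
            "heatmap_downsample": self.heatmap_downsample,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "screen" in d:
            kwargs["screen"] = ScreenGeometry.from_dict(d["screen"])
        if "camera" in d:
            kwargs["intrinsics"] = CameraIntrinsics.from_dict(d["camera"])
        if "tracker" in d:
            kwargs["tracker"] = TrackerConfig(**d["tracker"])
        if "ivt" in d:
            kwargs["ivt"] = IVTConfig(**d["ivt"])
        for key in ("calibration_margin_px", "calibration_dwell_s", "head_mode",
                    "noise_sigma_px", "seed", "sample_rate_hz",
                    "heatmap_downsample"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def _scenario_for(task: str, config: SessionConfig, rig: RigConfig):
    if task == "fixation":
        return make_fixation_scenario(config.screen, head_mode=config.head_mode,
                                      rig=rig,
                                      sample_rate_hz=config.sample_rate_hz)
    if task == "pursuit_rect":
        return make_pursuit_scenario("rect", config.screen,
                                     head_mode=config.head_mode, rig=rig,
                                     sample_rate_hz=config.sample_rate_hz)
    if task == "pursuit_circle":
        return make_pursuit_scenario("circle", config.screen,
                                     head_mode=config.head_mode, rig=rig,
                                     sample_rate_hz=config.sample_rate_hz)
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def run_task(
    config: SessionConfig,
    task: str,
    out_dir,
    backend: str = "synthetic",
    landmarks_path=None,
    calibration_path=None,
    truth_path=None,
) -> dict:
    """Execute calibrate -> track -> metrics and write all artifacts.

    ``backend="synthetic"`` renders the task on the rig (closed loop with
    ground truth); ``backend="replay"`` tracks a recorded landmark log using
    a saved calibration.  Returns ``{"artifacts": {...}, "report": {...},
    "fixation_stats": {...}}``.  A calibration stability failure raises
    :class:`CalibrationError` (the caller should ask the user to recalibrate).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    report = None

    if backend == "synthetic":
        rig = RigConfig(screen=config.screen, intrinsics=config.intrinsics)
        scenario = _scenario_for(task, config, rig)
        logger.info("running synthetic task %s (%.0f s at %.0f Hz, head %s)",
                    task, scenario.duration_s, scenario.sample_rate_hz,
                    config.head_mode)
        result = run_closed_loop(scenario, rig, config.tracker,
                                 noise_sigma_px=config.noise_sigma_px,
                                 seed=config.seed,
                                 calibration_dwell_s=config.calibration_dwell_s)
        samples = result.samples
        calibration = result.calibration
        report = result.report
        # persist the rendered landmarks for replay
        stream = ScenarioStream(scenario, rig, config.noise_sigma_px,
                                seed=int(np.random.SeedSequence(config.seed)
                                         .generate_state(2)[1]))
        write_landmark_log(stream.frames(), out / "landmarks.csv",
                           sidecar={"seed": config.seed, "task": task})
        artifacts["landmarks"] = str(out / "landmarks.csv")
        with open(out / "truth.csv", "w") as fh:
            fh.write("timestamp_s,target_x_px,target_y_px,yaw_deg,pitch_deg,roll_deg\n")
            for t, tgt, pose in zip(scenario.times(), result.truth_targets,
                                    result.truth_poses):
                fh.write(f"{float(t)!r},{float(tgt[0])!r},{float(tgt[1])!r},"
                         f"{float(pose.yaw)!r},{float(pose.pitch)!r},"
                         f"{float(pose.roll)!r}\n")
        artifacts["truth"] = str(out / "truth.csv")
    elif backend == "replay":
        if landmarks_path is None or calibration_path is None:
            raise ValueError("replay backend needs landmarks_path and "
                             "calibration_path")
        calibration = CalibrationResult.from_json(calibration_path)
        samples = list(track(landmark_stream(landmarks_path), calibration,
                             config.intrinsics, config.screen, config.tracker))
        if truth_path is not None:
            import pandas as pd
            tdf = pd.read_csv(truth_path)
            report = accuracy_report(
                samples, tdf[["target_x_px", "target_y_px"]].to_numpy(),
                config.screen)
    else:
        raise ValueError(f"backend must be 'synthetic' or 'replay': {backend!r}")

    calibration.to_json(out / "calibration.json")
    artifacts["calibration"] = str(out / "calibration.json")
    write_gaze_log(samples, out / "gaze.csv", calibration=calibration,
                   screen=config.screen, config=config.tracker)
    artifacts["gaze"] = str(out / "gaze.csv")

    labels, events = ivt_classify(samples, config.screen, config.ivt)
    write_fixation_events(events, out / "events.csv")
    artifacts["events"] = str(out / "events.csv")
    stats = fixation_stats(events)

    try:
        grid = build_heatmap(samples, config.screen,
                             grid_downsample=config.heatmap_downsample)
        grid.save_txt(out / "heatmap.txt")
        render_heatmap_png(grid, out / "heatmap.png")
        artifacts["heatmap"] = str(out / "heatmap.png")
        artifacts["heatmap_matrix"] = str(out / "heatmap.txt")
    except MetricsError:
        logger.warning("no valid samples; heatmap skipped")

    bundle = {"task": task, "backend": backend, "fixation_stats": stats,
              "config": config.to_dict()}
    if report is not None:
        bundle["accuracy"] = report
    save_report(bundle, out / "report.json")
    artifacts["report"] = str(out / "report.json")
    return {"artifacts": artifacts, "report": report, "fixation_stats": stats}
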