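"""Exception hierarchy for camgaze."""


class CamgazeError(Exception):
    """Base class for all camgaze errors."""


class GeometryError(CamgazeError):
    """Invalid or degenerate geometric configuration."""


class CameraCalibrationError(CamgazeError):
    """Intrinsic camera calibration failed (too few views, rank deficiency...)."""


class FeatureExtractionError(CamgazeError):
    """A required facial/iris landmark is missing from a frame."""

    def __init__(self, missing_index: int, message: str | None = None):
        self.missing_index = missing_index
        super().__init__(message or f"required landmark index {missing_index} is missing")


class StreamError(CamgazeError):
    """Malformed landmark stream (unknown backend, non-monotonic timestamps...)."""


class CalibrationError(CamgazeError):
    """Five-point gaze calibration failed; the user must recalibrate."""


class MetricsError(CamgazeError):
    """Analytics cannot be computed from the provided samples."""


class RenderError(CamgazeError):
    """The synthetic rig cannot render the requested configuration."""
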