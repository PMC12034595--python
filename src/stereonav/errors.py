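"""Exception hierarchy.

Every error raised by the library derives from :class:`StereoNavError`
so callers can catch pipeline failures with a single except clause while
still distinguishing individual failure modes.
"""


class StereoNavError(Exception):
    """Base class for all stereonav errors."""


class InvalidBaselineError(StereoNavError, ValueError):
    """Stereo baseline T_x is zero (reprojection matrix undefined)."""


class InvalidIntrinsicsError(StereoNavError, ValueError):
    """Camera intrinsics violate their invariants (e.g. f <= 0)."""


class BehindCameraError(StereoNavError, ValueError):
    """A 3D point with Z <= 0 cannot be projected."""


class ConvergenceError(StereoNavError, RuntimeError):
    """An iterative routine (e.g. undistortion) failed to converge."""


class CalibrationDegenerateError(StereoNavError, ValueError):
    """Too few or degenerate checkerboard views for calibration."""


class InterlaceParityError(StereoNavError, ValueError):
    """Interlaced frame has an odd number of rows."""


class NotRectifiedError(StereoNavError, ValueError):
    """Operation requires a rectified stereo frame."""


class DimensionMismatchError(StereoNavError, ValueError):
    """Array/image dimensions do not agree."""


class PointAtInfinityError(StereoNavError, ValueError):
    """Zero disparity reprojects to infinity."""


class DegenerateReprojectionError(StereoNavError, ValueError):
    """Homogeneous reprojection produced W = 0."""


class NoDepthAtLandmarkError(StereoNavError, ValueError):
    """No valid disparity in the picking window (point-cloud gap)."""


class InsufficientLandmarksError(StereoNavError, ValueError):
    """Rigid registration needs at least three landmark pairs."""


class DegenerateConfigurationError(StereoNavError, ValueError):
    """Collinear landmarks leave the rotation unconstrained."""


class MeshError(StereoNavError, ValueError):
    """Malformed or unsupported mesh data/file."""


class LandmarkFileError(StereoNavError, ValueError):
    """Malformed fiducial file (missing columns, duplicate names...)."""


class ConfigError(StereoNavError, ValueError):
    """Invalid pipeline configuration."""
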