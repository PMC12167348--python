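"""Exception hierarchy shared across the toolkit."""

from __future__ import annotations


class EndonavError(Exception):
    """Base class for all toolkit errors."""


class InvalidTransformError(EndonavError, ValueError):
    """Rotation not orthonormal / determinant not +1, or malformed pose data."""


class DegenerateGeometryError(EndonavError, ValueError):
    """Point configuration is geometrically degenerate (collinear, rank-deficient...)."""


class CalibrationError(EndonavError, RuntimeError):
    """Camera calibration failed (too few views, degenerate view set...)."""


class InsufficientMarkersError(EndonavError, RuntimeError):
    """Fewer board points detected than the configured minimum.

    Deliberately distinct from :class:`DegenerateGeometryError`: enough points
    were requested but not observed, as opposed to observed-but-degenerate.
    """


class NoOverlapError(EndonavError, RuntimeError):
    """ICP found zero correspondences within the distance gate.

    Carries the last transform estimate so callers can inspect where the
    alignment diverged.
    """

    def __init__(self, message: str, last_transform=None):
        super().__init__(message)
        self.last_transform = last_transform


class NoVisibleTargetsError(EndonavError, RuntimeError):
    """No evaluation target is visible in both the truth and estimate chains."""


class InsufficientDataError(EndonavError, ValueError):
    """Not enough samples/frames/points to run the requested operation."""
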