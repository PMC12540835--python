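"""Exception hierarchy for congresskit.

Every precondition violation defined by the analysis contracts maps to a
distinct exception so callers (and the CLI) can skip cells with a
machine-readable reason instead of silently dropping them.
"""


class CongresskitError(Exception):
    """Base class for all congresskit errors."""


class SchemaError(CongresskitError):
    """A tabular input violates the declared schema (names row/column)."""


class EmptyOverlapError(CongresskitError):
    """Two trajectories share no frames after gap interpolation."""


class DegenerateSpindleError(CongresskitError):
    """Pole separation never exceeds the minimum on any frame."""


class UndefinedFrameError(CongresskitError):
    """A per-frame quantity was requested on a frame with no defined spindle."""


class UndefinedAngleError(CongresskitError):
    """Angle requested for coincident points (direction undefined)."""


class EmptyKinematicsError(CongresskitError):
    """No frame has both sisters and the spindle frame defined."""


class InsufficientWindowError(CongresskitError):
    """Velocity window coverage before plate crossing is below half the window."""


class UndefinedDenominatorError(CongresskitError):
    """A fraction was requested with an empty denominator group."""


class NormalizationError(CongresskitError):
    """Reference intensity non-positive or aligned group empty."""
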