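"""Exception hierarchy shared by all reachsmooth modules.

Every error raised by the library derives from :class:`ReachSmoothError`,
so callers (and the CLI) can distinguish "your input file is malformed"
from "the recording does not contain enough usable movement".
"""


class ReachSmoothError(Exception):
    """Base class for all reachsmooth errors."""


class FormatError(ReachSmoothError):
    """Input file does not match the expected CSV dialect."""


class SamplingError(ReachSmoothError):
    """Timestamps are not uniform within tolerance."""


class ValidationError(ReachSmoothError):
    """Data violates a structural invariant (NaNs, empty series, ...)."""


class ParameterError(ReachSmoothError):
    """A parameter is outside its valid range."""


class RangeError(ReachSmoothError):
    """A window or index falls outside the recording."""


class LengthError(ReachSmoothError):
    """Series too short for the requested operation."""


class AlignmentError(ReachSmoothError):
    """Derived series do not share a common length/time base."""


class InsufficientDataError(ReachSmoothError):
    """Too few usable samples to compute a statistic reliably."""


class DegenerateSegmentError(ReachSmoothError):
    """Segment has zero duration, amplitude, or endpoint distance."""


class SegmentationFailure(ReachSmoothError):
    """No movement segment survived the amplitude filter.

    Mirrors the clinical situation of a participant whose movement is
    continuous and cannot be decomposed into single strokes.
    """


class NoMovementError(ReachSmoothError):
    """Speed profile contains no movement at all."""


class UndefinedCorrelationError(ReachSmoothError):
    """Correlation undefined (zero rank variance in one argument)."""


class RankError(ReachSmoothError):
    """Positions are degenerate (zero variance); no principal axes exist."""
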