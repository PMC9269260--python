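"""Exception hierarchy.

Everything raised deliberately by keykin derives from :class:`KeykinError`,
so callers can catch one type at pipeline boundaries.
"""


class KeykinError(Exception):
    """Base class for all keykin errors."""


class CalibrationError(KeykinError):
    """A key in the stream has no calibration entry."""


class DegenerateCalibrationError(CalibrationError):
    """neutral_count == bottom_count: the linear map is undefined."""


class InsufficientDataError(KeykinError):
    """Fewer samples/strokes/chords than the operation requires."""


class ClockError(KeykinError):
    """Timestamps are not strictly increasing."""


class NonUniformSamplingError(KeykinError):
    """Operation requires a uniform grid; resample first."""


class ConfigurationError(KeykinError):
    """Missing or inconsistent configuration (depth range, shape name, ...)."""


class DegenerateInputError(KeykinError):
    """Input with no usable variation (identical depths, zero variance, ...)."""


class InvariantViolationError(KeykinError):
    """A domain invariant (e.g. event ordering) does not hold."""


class InsufficientStrokesError(InsufficientDataError):
    """Trial statistics need at least two complete strokes."""


class PairingError(KeykinError):
    """Chord pairing failed (no overlapping strokes to pair)."""


class DegenerateColumnError(DegenerateInputError):
    """A table column has zero variance; standardization is undefined."""


class FittingError(KeykinError):
    """Penalized regression could not be fitted."""


class InfeasibleRateError(ConfigurationError):
    """Requested strike rate leaves no room for the keystroke cycle."""
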