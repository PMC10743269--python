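"""Exception types raised by the crckit pipeline.

All data-shape problems derive from :class:`ValueError` so callers that do not
care about the fine distinction can catch one base class; subject-level
exclusions derive from :class:`RuntimeError` because they are a property of a
subject/trial, not of a single array.
"""


class CrcError(Exception):
    """Base class for all crckit-specific errors."""


class FormatError(CrcError, ValueError):
    """An input file could not be parsed in the declared format."""


class OrderingError(CrcError, ValueError):
    """Event or interval timestamps are not strictly increasing."""


class InsufficientDataError(CrcError, ValueError):
    """Too few events/intervals/samples for the requested operation."""


class ExtrapolationError(CrcError, ValueError):
    """A resampling grid extends beyond the span of the data."""


class DegenerateDataError(CrcError, ValueError):
    """Values have zero range; histogram edges cannot be built."""


class OutOfRangeError(CrcError, ValueError):
    """A value lies outside the histogram edges."""


class AlphabetError(CrcError, ValueError):
    """Two distributions do not share a common bin alphabet."""


class PairingError(CrcError, ValueError):
    """Paired arrays have mismatched lengths."""


class BalanceError(CrcError, ValueError):
    """The majority condition has fewer samples than the minority one."""


class SubjectExcludedError(CrcError, RuntimeError):
    """A subject (or subject-trial) has too little bradycardic data to use."""


class DegenerateTestError(CrcError, ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


class CohortError(CrcError, RuntimeError):
    """No subject in the cohort produced usable results."""
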