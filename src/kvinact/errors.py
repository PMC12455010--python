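"""Exception hierarchy.

Everything raised on bad user input derives from :class:`KvinactError` so
callers (and the CLI) can distinguish package errors from bugs.
"""


class KvinactError(Exception):
    """Base class for all kvinact errors."""


class ValidationError(KvinactError, ValueError):
    """A configuration or input value violates a documented invariant."""


class DomainError(KvinactError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class CohortFormatError(KvinactError, ValueError):
    """An on-disk cohort does not conform to the portable layout."""


class UnanalysableSweepError(KvinactError, ValueError):
    """A sweep cannot be normalized or measured (zero / negative peak)."""


class NoPeakAboveLevelError(UnanalysableSweepError):
    """The normalized trace never reaches the crossing level."""


class MissingSweepError(KvinactError, KeyError):
    """Requested step potential is absent from a recording."""


class UnknownConditionError(KvinactError, KeyError):
    """A referenced condition label does not occur in the data."""
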