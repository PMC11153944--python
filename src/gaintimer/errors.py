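"""Exception hierarchy.

All package-specific failures derive from :class:`GainTimerError` so callers
(and the CLI) can distinguish validation problems, untimeable copy number
states, and numerical pathologies by exception class.
"""


class GainTimerError(Exception):
    """Base class for all package errors."""


class UnsupportedStateError(GainTimerError):
    """Copy number state outside the supported range (major 2..10, minor 0..2)."""


class UntimeableStateError(GainTimerError):
    """State whose timing system has no unique solution (e.g. minor 2 without WGD)."""


class TooFewMutationsError(GainTimerError):
    """Fewer than the minimum number of mutations required to time a segment."""


class DegenerateSystemError(GainTimerError):
    """The timing linear system is singular."""


class NonPositiveRateError(GainTimerError):
    """The solved mutation-rate scale is zero or negative; estimates are meaningless."""


class InvalidParameterError(GainTimerError):
    """A parameter is outside its admissible range (purity, bootstrap count, ...)."""


class ContextUnavailableError(GainTimerError):
    """Trinucleotide context is required but neither annotated nor derivable."""


class MissingAnnotationError(GainTimerError):
    """A filter mode requires an annotation column that is absent."""


class ValidationError(GainTimerError):
    """Malformed input file or record; message names the offending line."""
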