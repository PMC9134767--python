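"""Exception hierarchy shared across the package.

Errors are deliberately specific: a caller that batches many cells needs to
distinguish a malformed file from a region that merely failed a quality
check, because the latter is flagged in the output table rather than
aborting the run.
"""


class ChromasymError(Exception):
    """Base class for all package errors."""


class FormatError(ChromasymError):
    """A file could not be interpreted (bad shape, channel mismatch, ...)."""


class MissingChannelError(ChromasymError, KeyError):
    """A named channel is absent from the stack."""


class EmptyRegionError(ChromasymError):
    """A region rasterized to zero pixels on some required slice."""


class ContractError(ChromasymError):
    """Inputs violate a documented precondition (e.g. ROI area mismatch)."""


class SpecError(ChromasymError):
    """A synthetic-data spec is internally inconsistent."""


class UndefinedRatioError(ChromasymError):
    """A ratio's denominator is non-positive; the row is flagged, not dropped."""


class AmbiguousStrandError(ChromasymError):
    """PCNA means tie exactly; the segment is excluded rather than guessed."""


class InvalidSegmentError(ChromasymError):
    """Background-subtracted strand intensity is non-positive."""


class DegenerateStatisticError(ChromasymError):
    """A statistic is undefined for the input (n too small, zero variance)."""
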