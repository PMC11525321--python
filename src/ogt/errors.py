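"""Exception types raised across the pipeline.

All inherit from :class:`OgtError` (itself a ``ValueError``) so callers can
catch either the specific condition or anything the package raises.
"""


class OgtError(ValueError):
    """Base class for all errors raised by :mod:`ogt`."""


class ParseError(OgtError):
    """A file could not be parsed under the requested dialect."""


class RangeError(OgtError):
    """A value fell outside the annotation scale bounds."""


class DegenerateInputError(OgtError):
    """Input too small or otherwise degenerate for the operation."""


class ShapeError(OgtError):
    """Sequence lengths or shapes are incompatible."""


class UndefinedAgreementError(OgtError):
    """An agreement metric is undefined on the given input (e.g. no valid step)."""


class UndefinedMetricError(OgtError):
    """A classical metric is undefined (e.g. constant input)."""


class AlignmentInfeasibleError(OgtError):
    """No warp path exists under the requested temporal-distortion band."""


class SelectionImpossibleError(OgtError):
    """Inlier selection cannot proceed (e.g. all pairwise agreements undefined)."""


class BudgetTooLargeError(OgtError):
    """A segment budget exceeds what the sample count can represent."""


class ExhaustedPairsError(OgtError):
    """All unordered region pairs have already been asked."""


class NoInformationError(OgtError):
    """An embedding was requested with no triplets to constrain it."""


class ReconstructionImpossibleError(OgtError):
    """Ground-truth reconstruction requires at least one flat region."""
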