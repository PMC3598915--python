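"""Exception hierarchy for survtransfer.

All package errors derive from :class:`SurvTransferError` so callers can
catch one base class; subclasses mirror the failure modes of the public API
(invalid configuration, degenerate inputs, model-fitting failures, I/O schema
violations).
"""


class SurvTransferError(Exception):
    """Base class for all survtransfer errors."""


class ConfigurationError(SurvTransferError):
    """A configuration object is invalid; the message names the field."""


class InputError(SurvTransferError):
    """Empty or malformed in-memory input (e.g. no outcomes)."""


class DesignError(SurvTransferError):
    """Invalid design matrix: dimension mismatch, constant column, n <= p."""


class ConvergenceError(SurvTransferError):
    """Model fitting failed to converge; carries diagnostics in the message."""


class DegenerateGroupingError(SurvTransferError):
    """A two-sample comparison received an empty group."""


class UndefinedStatisticError(SurvTransferError):
    """A statistic is undefined for the given input (e.g. no usable pairs,
    constant scores, no cases or no controls at the evaluation time)."""


class EmptySignatureError(SurvTransferError):
    """Univariate screening selected zero genes; relax the threshold."""


class SignatureCoverageError(SurvTransferError):
    """A dataset is missing genes required by a model's signature."""


class RoutingError(SurvTransferError):
    """A survival-tree could not route a sample (unseen categorical level)."""


class SchemaError(SurvTransferError):
    """An input file violates the expected schema; names the column/location."""


class AlignmentError(SurvTransferError):
    """Clinical and expression files share no samples, or ids misalign."""
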