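"""Exception hierarchy for the myelinlfq pipeline.

Every stage raises a subclass of :class:`MyelinLFQError` so that pipeline
orchestration can attach the stage name while propagating.
"""


class MyelinLFQError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(MyelinLFQError):
    """Experimental design does not meet the minimal replication contract."""


class ConfigError(MyelinLFQError):
    """Inconsistent or out-of-range configuration values."""


class SchemaError(MyelinLFQError):
    """Matrix / design / table column mismatch."""


class AlphabetError(MyelinLFQError):
    """Protein sequence contains characters outside the 20-letter alphabet."""


class EmptyInputError(MyelinLFQError):
    """An input that must be non-empty is empty."""


class DegenerateInputError(MyelinLFQError):
    """Input is formally valid but the requested quantity is undefined on it."""


class TransformError(MyelinLFQError):
    """A value transform (e.g. log2) is undefined for an observed cell."""


class PipelineOrderError(MyelinLFQError):
    """A stage was called before its prerequisite stage (e.g. normalization
    before imputation)."""


class ImputationError(MyelinLFQError):
    """Imputation impossible for a target cell (e.g. fully-missing column)."""


class InsufficientDataError(MyelinLFQError):
    """Too few observations to compute the requested statistic."""


class MembershipError(MyelinLFQError):
    """Set-membership precondition violated (e.g. study set not contained in
    the background)."""


class EmptyMaskError(MyelinLFQError):
    """A pixel mask that must contain at least one positive pixel is empty."""
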