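"""Exception hierarchy shared across the package."""


class AmplicloneError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AmplicloneError):
    """A count table file does not conform to the expected dialect."""


class ValidationError(AmplicloneError):
    """A record violates a structural invariant (e.g. alt_reads > total_reads)."""


class UndefinedFractionError(AmplicloneError):
    """An allele fraction was requested for a sample with zero total reads."""


class InsufficientDataError(AmplicloneError):
    """Too few observations for the requested estimate."""


class CohortMismatchError(AmplicloneError):
    """A reference-only operation received non-reference samples."""


class EmptySelectionError(AmplicloneError):
    """A filter (e.g. passage) matched no samples."""


class DesignDegeneracyError(AmplicloneError):
    """The regression design is degenerate (e.g. a single passage value)."""


class GroupingError(AmplicloneError):
    """Association requires exactly two non-reference groups."""


class EmptyReportError(AmplicloneError):
    """A report was requested for an empty call set."""


class PipelineError(AmplicloneError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
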