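"""Exception hierarchy for the pipeline."""


class CiasPipeError(Exception):
    """Base class for all package errors."""


class ConfigError(CiasPipeError):
    """Invalid configuration value (probability out of range, non-positive SD, ...)."""


class OutOfCoverageError(CiasPipeError):
    """Age falls outside every normative band."""


class SchemaError(CiasPipeError):
    """Unknown subtest, timepoint, or malformed column layout."""


class DataIntegrityError(CiasPipeError):
    """Duplicate identifiers or otherwise inconsistent records."""


class NotComputableError(CiasPipeError):
    """A quantity cannot be computed from an incomplete panel/record."""


class InsufficientSampleError(CiasPipeError):
    """Too few observations for the requested estimator."""


class DegenerateDesignError(CiasPipeError):
    """Rank-deficient design matrix after level pruning."""


class ZeroVarianceError(CiasPipeError):
    """A regression predictor has zero variance: slope undefined."""


class PipelineStageError(CiasPipeError):
    """A pipeline stage failed; carries the stage name and offending records."""

    def __init__(self, stage: str, message: str, records=None):
        self.stage = stage
        self.records = list(records) if records is not None else []
        detail = f" offending records: {self.records}" if self.records else ""
        super().__init__(f"stage '{stage}' failed: {message}.{detail}")


class EmptyAnalysisError(CiasPipeError):
    """No patients remain after filtering; report is written with headers only."""
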