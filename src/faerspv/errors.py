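"""Exception types shared across the pipeline."""


class FaerspvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FaerspvError):
    """A table header does not match the declared schema."""

    def __init__(self, table_id: str, missing: list[str]):
        self.table_id = table_id
        self.missing = list(missing)
        super().__init__(
            f"{table_id}: header is missing required columns {sorted(self.missing)}"
        )


class ConfigurationError(FaerspvError):
    """An invalid generator or pipeline configuration."""


class InsufficientDataError(FaerspvError):
    """Too few observations for the requested fit."""


class DegenerateSampleError(FaerspvError):
    """A sample on which the model is not identifiable (e.g. all values tied)."""


class PipelineStageError(FaerspvError):
    """A pipeline stage failed; carries the stage name and row-count context."""

    def __init__(self, stage: str, n_in: int, cause: Exception):
        self.stage = stage
        self.n_in = n_in
        self.cause = cause
        super().__init__(f"stage {stage!r} failed with {n_in} input reports: {cause}")
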