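"""Exception types raised across the package.

Every error message names the offending column, row, config key or stage so
that failures on real tables are actionable without a debugger.
"""


class RetclustError(Exception):
    """Base class for all package errors."""


class SchemaError(RetclustError):
    """A required column is missing from an input table."""


class TableValidationError(RetclustError):
    """A cell-table row violates an invariant (coordinates, ids, flags)."""


class ConfigError(RetclustError):
    """A configuration value is missing, malformed or out of range."""


class ConsistencyError(RetclustError):
    """Cross-references between objects do not resolve (e.g. member ids)."""


class PackingError(RetclustError):
    """Requested cluster centers cannot be placed at the inhibition radius."""


class PipelineStageError(RetclustError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
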