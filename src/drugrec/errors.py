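"""Exception types shared across the package."""


class DrugRecError(Exception):
    """Base class for package errors."""


class SchemaError(DrugRecError):
    """Input table does not conform to the expected encounter schema."""


class RowParseError(DrugRecError):
    """A specific data row could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ConfigError(DrugRecError):
    """Invalid configuration value."""


class PipelineStageError(DrugRecError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
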