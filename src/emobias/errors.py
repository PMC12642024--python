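"""Exception hierarchy shared across the pipeline."""


class EmobiasError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EmobiasError):
    """A required column is missing or a table has the wrong shape."""


class TableValidationError(EmobiasError):
    """A row-level validation failure; carries the offending row number.

    ``row`` is the 1-based data-row index (header excluded) so the message
    points at the line a user would see in a spreadsheet minus one.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ConfigError(EmobiasError):
    """Invalid or degenerate configuration."""


class DegenerateDataError(EmobiasError):
    """Input data carry no usable signal (constant vector, zero trials...)."""


class InsufficientDataError(EmobiasError):
    """Not enough data to attempt a fit at all."""


class SingularDesignError(EmobiasError):
    """Regression design matrix is rank deficient."""


class StageError(EmobiasError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
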