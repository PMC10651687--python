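"""Exception hierarchy shared across the pipeline stages."""


class TmtCycleError(Exception):
    """Base class for all package errors."""


class ParameterError(TmtCycleError, ValueError):
    """A simulation or analysis parameter is invalid (non-finite, out of range)."""


class SizingError(TmtCycleError, ValueError):
    """The requested design does not fit the available labeling capacity."""


class SchemaError(TmtCycleError, ValueError):
    """An input table is missing required columns or samples."""


class IntegrityError(TmtCycleError, ValueError):
    """Duplicate identifiers or inconsistent table dimensions."""


class DesignError(TmtCycleError, ValueError):
    """A statistical design requirement is violated (group sizes, empty cells)."""


class DataError(TmtCycleError, ValueError):
    """A feature is missing required upstream results."""


class ParseError(TmtCycleError, ValueError):
    """A text input could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IdentifiabilityError(TmtCycleError, ValueError):
    """A model cannot be identified from the given design (rank deficiency)."""


class DegenerateInputError(TmtCycleError, ValueError):
    """Input has no usable variation (e.g. constant matrix for PCA)."""
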