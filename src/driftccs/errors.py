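"""Exception hierarchy shared by all modules."""


class DriftCCSError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DriftCCSError, ValueError):
    """A physically meaningless argument (non-positive mass, pressure, ...)."""


class SchemaError(DriftCCSError):
    """An input table is missing a required column or attribute."""


class RowParseError(DriftCCSError):
    """A row of an input table could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class IntegrityError(DriftCCSError):
    """Duplicate keys or otherwise inconsistent metadata."""


class InsufficientDataError(DriftCCSError):
    """Too few fields, calibrants or points to fit the requested model."""


class CalibrationError(DriftCCSError):
    """A calibration fit produced an unusable model (e.g. negative slope)."""


class AssignmentError(DriftCCSError):
    """No calibration run could be assigned to a sample run."""


class ConfigError(DriftCCSError):
    """Invalid run configuration."""
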