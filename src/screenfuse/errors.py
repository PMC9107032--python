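"""Exception hierarchy.

Errors are split by provenance so callers (and the CLI exit-code mapping)
can distinguish bad configuration from bad data from undefined numerics.
"""


class ScreenfuseError(Exception):
    """Base class for all package errors."""


class ConfigError(ScreenfuseError):
    """Invalid or inconsistent run configuration."""


class SchemaError(ScreenfuseError):
    """A table is missing required columns or has wrong dtypes."""


class ParseError(ScreenfuseError):
    """A cell value is outside its enumeration; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class IntegrityError(ScreenfuseError):
    """A record violates a cross-field invariant (e.g. the question cascade)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class AlignmentError(ScreenfuseError):
    """Two score vectors or tables that must be aligned are not."""


class MetricUndefinedError(ScreenfuseError):
    """A discrimination metric is undefined for the given labels (one class)."""
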