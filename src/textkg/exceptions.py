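"""Exception hierarchy shared across the package."""


class TextKGError(Exception):
    """Base class for all package errors."""


class ConfigError(TextKGError, ValueError):
    """An invalid configuration value or inconsistent combination of values."""


class DataError(TextKGError, ValueError):
    """Input data violates a contract (wrong labels, ragged shapes, empty input)."""


class ParseError(TextKGError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
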