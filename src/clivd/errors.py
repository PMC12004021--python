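"""Exception hierarchy shared across the package."""


class ClivdError(Exception):
    """Base class for all package errors."""


class ParseError(ClivdError):
    """A record file line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(ClivdError):
    """An event or stream violates a data-model invariant."""


class ConfigError(ClivdError):
    """A configuration file or parameter set is invalid."""


class DomainError(ClivdError):
    """An operation was called outside its scientific domain (e.g. under-age query)."""


class ConsistencyError(ClivdError):
    """An internal invariant failed (e.g. non-monotone risk interval)."""
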