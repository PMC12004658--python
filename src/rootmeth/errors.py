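"""Exception types shared across the pipeline stages."""


class RootmethError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RootmethError):
    """An invalid or infeasible configuration value."""


class ParseError(RootmethError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(RootmethError):
    """Data that parses but violates an invariant (e.g. mc > cov)."""


class InsufficientDataError(RootmethError):
    """Too few observations for the requested statistic."""
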