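"""Exception types shared across the pipeline."""


class ClanOverlapError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ClanOverlapError, ValueError):
    """A line of an input file could not be parsed.

    Carries the offending line number (1-based) when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(ClanOverlapError, ValueError):
    """A record was parsed but violates a domain-type invariant."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigError(ClanOverlapError, ValueError):
    """A scenario configuration is internally inconsistent or infeasible."""


class UndefinedResultError(ClanOverlapError, ValueError):
    """The requested statistic is undefined for this input (e.g. empty set)."""
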