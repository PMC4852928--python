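"""Typed exceptions shared across the package."""


class CodephenError(Exception):
    """Base class for all package errors."""


class InputFormatError(CodephenError):
    """A flat input file violates the expected layout (header, types, invariants).

    ``lines`` carries the 1-based line numbers of the offending rows when known.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        self.lines = lines or []
        if self.lines:
            message = f"{message} (line{'s' if len(self.lines) > 1 else ''} {', '.join(map(str, self.lines))})"
        super().__init__(message)


class DegenerateInputError(CodephenError):
    """An operation received input it cannot act on (e.g. a single-class cohort)."""


class ConfigurationError(CodephenError):
    """A configuration object or file is incomplete or inconsistent."""
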