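"""Exception hierarchy for annotation parsing, configuration and computation."""


class EpgError(Exception):
    """Base class for all package errors."""


class ParseError(EpgError):
    """A line or row of an annotation file could not be interpreted."""

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class FormatError(EpgError):
    """The file parsed but violates a structural requirement of the format
    (missing terminal mark, non-monotone timestamps, too few marks)."""

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ConfigError(EpgError):
    """Invalid configuration (unknown acronym, inconsistent options)."""


class UsageError(EpgError):
    """The caller supplied unusable arguments (e.g. an empty file list)."""


class DomainError(EpgError):
    """A numeric argument is outside its mathematical domain."""


class ValidationFailed(EpgError):
    """Variable computation refused because the mark sequence has unresolved
    grammar issues and ``force`` was not set."""

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = issues or []


class GenerationError(EpgError):
    """The synthetic-recording profile is infeasible."""


class InjectionSkip(EpgError):
    """The requested grammar violation cannot be injected into this recording
    (e.g. no potential-drop group exists to corrupt)."""
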