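"""Exception hierarchy shared across the package."""


class MethContextError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethContextError):
    """A file violates its format contract.

    Carries the 1-based line number of the first offending line when one
    can be identified.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PatternError(MethContextError):
    """A string does not match the required sequence pattern (e.g. NNCGNN)."""


class ConfigurationError(MethContextError):
    """Invalid configuration or mutually inconsistent inputs."""


class InsufficientDataError(MethContextError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(MethContextError):
    """The statistic is undefined on this input (zero variance, zero coverage)."""
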