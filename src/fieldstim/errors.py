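"""Exception hierarchy shared across the toolkit."""


class FieldStimError(Exception):
    """Base class for all toolkit errors."""


class DomainError(FieldStimError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UsageError(FieldStimError, ValueError):
    """An operation was called for a configuration it does not apply to."""


class ConfigError(FieldStimError, ValueError):
    """A protocol configuration is malformed (e.g. range min > max)."""


class ValidationError(FieldStimError, ValueError):
    """Settings failed device validation; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations) or "invalid settings"
        super().__init__(msg)


class SchedulingError(FieldStimError, RuntimeError):
    """A pulse cannot be realized at the requested phase/overhead setting."""


class ResolutionError(FieldStimError, ValueError):
    """Sample rate too low to resolve the shortest scheduled phase."""


class ParseError(FieldStimError, ValueError):
    """A trace or log file is malformed; carries the offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
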