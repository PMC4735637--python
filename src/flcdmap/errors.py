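"""Exception hierarchy shared across the package."""


class FlcdError(Exception):
    """Base class for all package errors."""


class ParameterError(FlcdError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class InputError(FlcdError, ValueError):
    """Input data violate a precondition (mismatched coordinates, bad range)."""


class SimulationError(FlcdError, RuntimeError):
    """A simulation could not produce a valid outcome (e.g. selection left
    no carriers within the retry budget)."""


class SyncParseError(FlcdError, ValueError):
    """A sync-format line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
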