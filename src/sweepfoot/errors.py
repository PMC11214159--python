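"""Exception hierarchy shared across the pipeline stages."""


class SweepfootError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SweepfootError):
    """Malformed or inconsistent user input (bad values, missing records)."""


class AlignmentError(InputError):
    """Sequences that are supposed to be aligned do not line up."""


class ConfigError(SweepfootError):
    """Invalid configuration value (non-positive window, bad rate, ...)."""


class EstimationError(SweepfootError):
    """A statistical estimate cannot be formed from the data given."""


class DegenerateModelError(SweepfootError):
    """A model fit is degenerate (zero residual variance, collinearity)."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
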