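"""Exception hierarchy shared across the package."""


class FFLTuneError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FFLTuneError, ValueError):
    """Input violates a documented precondition."""


class InvalidParameterError(ValidationError):
    """A model parameter is outside its admissible range."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested estimate."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but makes the statistic undefined
    (e.g. zero variance on the focal gene set)."""


class DivisionUndefinedError(FFLTuneError, ZeroDivisionError):
    """A ratio against a zero reference quantity was requested."""


class StopCodonError(ValidationError):
    """A stop codon appeared where a sense codon is required."""


class UndefinedLogError(ValidationError):
    """A log-ratio was requested at a time point with a zero count."""


class IntegrationError(FFLTuneError, RuntimeError):
    """Numerical integration of the ODE system failed."""


class FitConvergenceError(FFLTuneError, RuntimeError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
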