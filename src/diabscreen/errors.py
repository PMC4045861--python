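"""Exception hierarchy shared across the pipeline."""


class DiabscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(DiabscreenError):
    """A scenario configuration field is invalid; the message names the field."""


class SchemaError(DiabscreenError):
    """Input table does not conform to the expected column layout."""


class MissingDataError(DiabscreenError):
    """A required value (lab test, covariate, visit count) is absent."""


class DegenerateDataError(DiabscreenError):
    """Data cannot support the requested computation (empty category, single class, zero total)."""


class ConvergenceError(DiabscreenError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_coef=None, n_iterations=None):
        super().__init__(message)
        self.last_coef = last_coef
        self.n_iterations = n_iterations
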