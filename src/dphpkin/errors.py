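"""Exception hierarchy used across the package."""


class DphpkinError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DphpkinError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(DphpkinError, ValueError):
    """A parameter/configuration value is inconsistent or unusable."""


class NumericalFailureError(DphpkinError, RuntimeError):
    """The ODE integrator (or another numerical routine) failed to converge."""


class FitFailureError(DphpkinError, ValueError):
    """A distribution back-fit could not reproduce the requested summaries.

    Carries the per-quantile relative residuals in ``residuals``.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals
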