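"""Exception types raised across the package."""


class CraneselError(Exception):
    """Base class for package errors."""


class ConfigurationError(CraneselError, ValueError):
    """Invalid generator or study configuration."""


class AnnotationError(CraneselError, ValueError):
    """A point could not be annotated with covariates."""


class StratumError(CraneselError, ValueError):
    """A matched stratum could not be constructed or is malformed."""


class SeparationError(CraneselError, RuntimeError):
    """The conditional likelihood is unbounded along some covariate."""

    def __init__(self, covariate: str, message: str | None = None):
        self.covariate = covariate
        super().__init__(
            message
            or f"Likelihood appears unbounded (separation) along covariate {covariate!r}"
        )
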