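"""Exception hierarchy shared across the pipeline stages."""


class FlumefishError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(FlumefishError):
    """Malformed input structure (mismatched lengths, non-increasing time, ...)."""


class DegenerateSeriesError(FlumefishError):
    """A velocity time series too short to carry fluctuation statistics."""


class OutOfDomainError(FlumefishError):
    """A query point outside the gridded test-area domain."""


class IncompleteSectionError(FlumefishError):
    """A monitoring cross-section with missing measurement points."""


class UndefinedAngleError(FlumefishError):
    """Movement-mode angle undefined because the local flow vector is zero."""


class UndefinedStatisticError(FlumefishError):
    """A statistic (correlation, concordance) undefined for the given input."""


class FitError(FlumefishError):
    """A model fit failed to converge or is inestimable."""


class ConfigError(FlumefishError):
    """Invalid or inconsistent configuration."""
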