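"""Exception hierarchy shared across the pipeline stages."""


class AtrophyForecastError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AtrophyForecastError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(AtrophyForecastError):
    """Metadata table violates the cohort schema."""


class EligibilityError(AtrophyForecastError):
    """A subject or scan violates a protocol eligibility rule."""


class ProtocolError(AtrophyForecastError):
    """An operation was applied to scans it must never touch."""


class FitError(AtrophyForecastError):
    """A model fit could not be completed."""


class DegenerateCovariateError(FitError):
    """A predictor is constant and carries no information."""


class CovariateError(AtrophyForecastError):
    """A required covariate is missing or has an unknown level."""


class AtlasError(AtrophyForecastError):
    """Atlas labels are missing, empty, or mismatched to the image grid."""


class DegeneratePredictionError(AtrophyForecastError):
    """A predictive distribution has zero spread and cannot be scored."""
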