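"""Exception hierarchy used across the package."""


class ActigutError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ActigutError, ValueError):
    """Invalid generator or pipeline configuration."""


class AlignmentError(ActigutError, ValueError):
    """Sample/participant identifiers do not line up between tables."""


class ResolutionError(ActigutError, ValueError):
    """Time series is not on the expected minute grid."""


class InsufficientDataError(ActigutError, ValueError):
    """Too few rows/strata to perform the requested computation."""


class DegenerateCompositionError(ActigutError, ValueError):
    """A compositional row or column makes a log-ratio undefined."""


class DomainError(ActigutError, ValueError):
    """Input values outside the mathematical domain of the operation."""
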