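"""Exception types shared across the pipeline."""


class EvpMirCompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EvpMirCompError):
    """Invalid user-supplied configuration or parameters."""


class FormatError(EvpMirCompError):
    """Malformed input file."""


class LinkageError(EvpMirCompError):
    """Sample identifiers do not line up between tables."""


class NormalizationError(EvpMirCompError):
    """Positive-control normalization cannot be computed."""


class DegenerateInputError(EvpMirCompError):
    """Statistically degenerate input (constant covariate, one-class outcome, ...)."""


class SeparationError(EvpMirCompError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(EvpMirCompError):
    """An iterative fit failed to converge."""
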