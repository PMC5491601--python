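"""Exception hierarchy for the rumenzeta pipeline.

Every stage raises a subclass of :class:`RumenZetaError`, so callers (and the
CLI) can catch one type and report the failing stage from the message.
"""


class RumenZetaError(Exception):
    """Base class for all package errors."""


class SchemaError(RumenZetaError):
    """A required column is missing or a table does not match its schema."""


class ParseError(RumenZetaError):
    """A cell could not be parsed as a number; names the row and column."""


class DesignValidationError(RumenZetaError):
    """A value is incompatible with the experimental design (off-grid time,
    unknown factor level)."""


class FeatureError(RumenZetaError):
    """A variable required by the feature configuration is unavailable."""


class DegenerateInputError(RumenZetaError):
    """Input admits no meaningful answer (constant target, all-zero mobility)."""


class FitError(RumenZetaError):
    """Model fitting preconditions violated or training diverged."""


class PredictionError(RumenZetaError):
    """Feature manifest of the data does not match the model's."""


class ConfigError(RumenZetaError):
    """Invalid generator or pipeline configuration."""


class SplitError(RumenZetaError):
    """Dataset too small to split."""
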