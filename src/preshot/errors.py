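"""Exception hierarchy shared across the pipeline stages."""


class PreshotError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PreshotError):
    """Invalid simulation or stage configuration."""


class FormatError(PreshotError):
    """Malformed or truncated on-disk file."""


class SchemaError(FormatError):
    """A required column is missing from a tabular file."""


class ValidationError(PreshotError):
    """Well-formed input with out-of-range or inconsistent values."""


class PipelineError(PreshotError):
    """A stage could not produce usable output (e.g. zero epochs)."""


class DesignError(PreshotError):
    """Statistical design unsuitable for the requested analysis."""
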