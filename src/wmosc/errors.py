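"""Exception types shared across the package."""


class WmoscError(Exception):
    """Base class for package errors."""


class ConfigurationError(WmoscError):
    """A configuration value is structurally invalid (bad schema, isolated
    channel, non-PSD correlation matrix, unknown column name, ...)."""


class DependencyError(WmoscError):
    """A pipeline stage is missing an upstream output."""


class StageError(WmoscError):
    """A pipeline stage failed during execution."""
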