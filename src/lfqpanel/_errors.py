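"""Exception hierarchy shared across the package."""


class LfqPanelError(Exception):
    """Base class for all package errors."""


class ValidationError(LfqPanelError):
    """Input data violates an invariant (bad value, duplicate key, ...)."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class ConfigError(ValidationError):
    """A configuration value is out of range or inconsistent."""
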