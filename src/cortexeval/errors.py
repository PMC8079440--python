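"""Exception types shared across the package."""


class CortexEvalError(Exception):
    """Base class for package errors."""


class ConfigurationError(CortexEvalError):
    """An invalid configuration value (negative scale, empty range, ...)."""


class SchemaError(CortexEvalError):
    """A table does not conform to the expected tidy schema."""


class NonIdentifiableError(CortexEvalError):
    """The requested model cannot be identified from the supplied design."""
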