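"""Exception hierarchy shared across the package."""


class GssaError(Exception):
    """Base class for all package errors."""


class FormatError(GssaError):
    """A file does not conform to its expected format."""


class ValidationError(GssaError):
    """Input data violates a documented precondition or invariant."""


class ConfigurationError(GssaError):
    """A run configuration value is unknown or inconsistent."""
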