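"""Exception types shared across the package."""


class ShoulderCoiError(Exception):
    """Base class for all package-specific errors."""


class InputError(ShoulderCoiError, ValueError):
    """Raised when input data violates a documented precondition."""


class ConfigurationError(ShoulderCoiError, ValueError):
    """Raised when a configuration value is invalid; the message names the field."""


class PackagingError(ShoulderCoiError, RuntimeError):
    """Raised when a packaged data resource is missing or corrupted."""
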