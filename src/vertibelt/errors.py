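"""Exception types shared across the package."""


class VertibeltError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VertibeltError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(VertibeltError, ValueError):
    """Invalid input data (bad composition string, unknown species code, ...)."""


class SampleSizeError(VertibeltError, ValueError):
    """Too few sample points to estimate cloud parameters."""


class InputError(VertibeltError, ValueError):
    """Missing or dimensionally incompatible input datasets."""
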