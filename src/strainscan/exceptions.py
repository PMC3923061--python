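"""Exception hierarchy shared across the package."""


class StrainscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StrainscanError, ValueError):
    """A configuration value is invalid or inconsistent."""


class DataError(StrainscanError, ValueError):
    """An input table violates a structural precondition."""


class FitError(StrainscanError, RuntimeError):
    """A fitting step could not produce a usable estimate."""
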