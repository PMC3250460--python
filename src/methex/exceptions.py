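"""Exception types shared across the package."""


class MethexError(ValueError):
    """Base class for all package-specific errors."""


class ConfigError(MethexError):
    """Raised when a simulation or pipeline configuration is invalid.

    The message names the offending field.
    """


class InputError(MethexError):
    """Raised when an input table violates its contract (bad values,
    duplicate identifiers, dimension mismatches, missing columns)."""
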