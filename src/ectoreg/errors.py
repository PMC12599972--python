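"""Exception types shared across the package."""


class EctoregError(Exception):
    """Base class for all package errors."""


class ParseError(EctoregError):
    """A file violates its format contract (names the offending line)."""


class FormatError(EctoregError):
    """Structurally valid input that breaks a semantic invariant."""


class ConfigError(EctoregError):
    """Invalid parameter combination."""


class SizingError(EctoregError):
    """A simulation design does not fit the requested genome."""
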