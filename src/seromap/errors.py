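"""Exception hierarchy shared across the package."""


class SeromapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeromapError):
    """A file does not conform to its declared dialect (missing column, empty table, ...)."""


class ValidationError(SeromapError):
    """A record violates a domain invariant (bad alphabet, inconsistent CDR3 bounds, ...)."""


class DesignError(SeromapError):
    """The experimental design is unusable (e.g. fewer than two replicates in a fraction)."""


class ConfigError(SeromapError):
    """A pipeline or simulation configuration value is unknown or out of range."""
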