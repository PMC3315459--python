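"""Exception types shared across the package."""


class RecimprintError(Exception):
    """Base class for package errors."""


class FormatError(RecimprintError, ValueError):
    """A file does not conform to its expected tabular/format schema."""


class ValidationError(RecimprintError, ValueError):
    """A field value violates a domain invariant (e.g. negative count)."""


class CrossReferenceError(RecimprintError, LookupError):
    """A record refers to an unknown entity, or a key is duplicated."""


class UndefinedTestError(RecimprintError, ValueError):
    """A statistic is requested on degenerate input (e.g. zero total reads)."""


class ConfigError(RecimprintError, ValueError):
    """A simulation or run configuration violates its invariants."""
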