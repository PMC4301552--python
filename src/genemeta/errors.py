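"""Exception hierarchy shared across the package."""


class GenemetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GenemetaError):
    """A delimited input does not match the documented column schema."""


class ValidationError(GenemetaError):
    """A study record violates a domain invariant (counts, ids, labels)."""


class ExclusionError(GenemetaError):
    """A study cannot contribute to a contrast (empty case or control margin)."""


class DegenerateDataError(GenemetaError):
    """Pooling input is degenerate (e.g. Mantel-Haenszel denominator is zero)."""
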