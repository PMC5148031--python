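"""Exception types shared across the package."""


class RifseqError(Exception):
    """Base class for all rifseq errors."""


class ValidationError(RifseqError, ValueError):
    """Malformed or inconsistent input data (never silently coerced)."""
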