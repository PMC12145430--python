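"""Exception types shared across the package."""


class PhenoforestError(Exception):
    """Base class for package-specific errors."""


class ParseError(PhenoforestError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PhenoforestError, ValueError):
    """An in-memory object violates one of its invariants."""


class ModelFormatError(PhenoforestError, ValueError):
    """A serialized model artifact is unreadable or from an incompatible version."""
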