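"""Exception types shared across the package."""


class FairspeechError(Exception):
    """Base class for all package errors."""


class ValidationError(FairspeechError, ValueError):
    """An input violates a documented precondition."""


class SchemaError(FairspeechError, ValueError):
    """A table does not match the documented column schema."""
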