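"""Exception hierarchy shared across the pipeline."""


class OsasevError(Exception):
    """Base class for all package errors."""


class FormatError(OsasevError):
    """Unreadable or malformed input file."""


class ValidationError(OsasevError):
    """Input violates a documented precondition (bad annotations, parameters...)."""


class EmptyOutputError(OsasevError):
    """An operation produced no usable output (e.g. no kept sleep stages)."""
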