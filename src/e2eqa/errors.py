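"""Exception hierarchy for the QA toolkit."""


class E2EQAError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(E2EQAError, ValueError):
    """An input violates a precondition (geometry mismatch, bad parameter...)."""


class FormatError(E2EQAError, IOError):
    """A file could not be parsed as a supported volume format."""


class MappingError(E2EQAError, KeyError):
    """A label map contains a label with no entry in the name table."""


class UndefinedInputError(E2EQAError, ValueError):
    """The requested quantity is undefined for this input (e.g. empty mask)."""
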