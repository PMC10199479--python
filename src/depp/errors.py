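"""Exception hierarchy shared by all depp modules."""


class DeppError(Exception):
    """Base class for all errors raised by depp."""


class ValidationError(DeppError):
    """Input violates a domain precondition (bad residue, bad count, ...)."""


class EmptyInputError(DeppError):
    """A file or collection that must be non-empty is empty."""


class SchemaError(DeppError):
    """Tabular rows do not share a single column schema."""


class SchemaMismatchError(DeppError):
    """Feature columns presented to a model differ from the columns it was trained on."""
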