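"""Exception hierarchy.

Two broad families matter for the command-line layer: schema/usage problems
(wrong columns, bad flags) exit with code 2, data-invariant violations
(unequal sequence lengths, unannotated ids, empty inputs) with code 3.
"""


class PdakitError(Exception):
    """Base class for all package errors."""


class SchemaError(PdakitError):
    """A table or configuration does not have the required shape."""


class DuplicateIdError(SchemaError):
    """The same sequence id occurs more than once where ids must be unique."""


class DataError(PdakitError):
    """Input data violate a structural invariant."""


class AlignmentFormatError(DataError):
    """An alignment file is malformed (e.g. ragged sequence lengths)."""


class EmptyInputError(DataError):
    """A file or collection that must be non-empty is empty."""


class AnnotationLookupError(DataError):
    """A sequence id has no annotation entry."""
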