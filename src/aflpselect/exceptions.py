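"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad files, inconsistent
ids, out-of-range parameters) and maps to CLI exit code 2; everything else
raised by the library is an ``AflpSelectError`` (exit code 1).
"""


class AflpSelectError(Exception):
    """Base class for errors raised by aflpselect."""


class ValidationError(AflpSelectError):
    """Invalid input data or parameters."""


class StructuralError(ValidationError):
    """A file or table whose overall shape is wrong (ragged rows,
    duplicate labels, empty file)."""
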