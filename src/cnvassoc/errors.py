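"""Exception hierarchy.

``FormatError`` signals a malformed input file (bad column, bad literal,
duplicate key); ``ValidationError`` signals data that parses but violates a
semantic invariant (overlapping segments, incomplete twin pair, mismatched
region universes). The CLI maps them both to exit code 1; anything else is a
runtime failure (exit code 2).
"""


class CnvError(Exception):
    """Base class for all package-raised errors."""


class FormatError(CnvError):
    """An input file does not conform to its declared format."""


class ValidationError(CnvError):
    """Parsed data violates a domain invariant or precondition."""
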