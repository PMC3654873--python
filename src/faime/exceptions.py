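"""Exception hierarchy for faime."""


class FaimeError(Exception):
    """Base class for all faime-specific errors."""


class ParseError(FaimeError):
    """A file could not be parsed; the message names the offending location."""


class DuplicateIdError(FaimeError):
    """Duplicate gene/sample/probe identifiers where uniqueness is required."""


class FormatError(FaimeError):
    """A structured input file violates its format contract."""


class DegenerateSetError(FaimeError):
    """A gene set whose complement within the measured universe is empty."""


class EmptyCollectionError(FaimeError):
    """A geneset collection ended up with no usable sets."""
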