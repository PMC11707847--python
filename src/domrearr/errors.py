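"""Exception hierarchy.

All errors raised by the library derive from :class:`DomRearrError` so that
callers (notably the CLI) can map them onto stable exit codes.
"""


class DomRearrError(Exception):
    """Base class for all domrearr errors."""


class InputFormatError(DomRearrError):
    """A file could not be parsed (malformed line, bad format, duplicate ids)."""


class ConsistencyError(DomRearrError):
    """Inputs disagree with each other (e.g. a tree leaf without annotations)."""


class ChainValidationError(DomRearrError):
    """An event chain references a source arrangement that is not available."""
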