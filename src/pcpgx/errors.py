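"""Exception hierarchy.

Readers and operations raise :class:`ValidationError` when an input violates a
documented invariant (they never silently coerce), and :class:`ParseError`
when a file cannot be interpreted at all.
"""


class PcpgxError(Exception):
    """Base class for all package errors."""


class ParseError(PcpgxError):
    """A file could not be parsed; the message names the offending row/column."""


class ValidationError(PcpgxError):
    """An input violates a documented invariant."""
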