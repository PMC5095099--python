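"""Exception hierarchy.

All package-raised errors derive from :class:`GrnError` so callers can catch
one base class; the subclasses also derive from :class:`ValueError` where the
failure is an invalid argument, to stay friendly to generic callers.
"""


class GrnError(Exception):
    """Base class for all errors raised by bpgrn."""


class InvalidInputError(GrnError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedStatisticError(GrnError):
    """A network statistic is undefined for this graph (e.g. no edges)."""


class ParseError(GrnError, ValueError):
    """A file could not be parsed; the message names the offending location."""
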