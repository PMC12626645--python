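"""Exception hierarchy shared across the pipeline."""


class NetstabError(Exception):
    """Base class for all package errors."""


class ParseError(NetstabError, ValueError):
    """A file could not be parsed into a valid table/tree."""


class InvalidInputError(NetstabError, ValueError):
    """Input violates a precondition of an operation."""


class EmptyResultError(NetstabError, ValueError):
    """An operation produced an empty result that downstream stages cannot use."""


class GenerationError(NetstabError, RuntimeError):
    """The synthetic-data generator could not produce a valid dataset."""
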