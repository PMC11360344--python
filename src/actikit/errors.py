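"""Exception hierarchy shared across the pipeline.

Two failure families matter operationally: malformed input data
(:class:`FormatError`, CLI exit status 2) and violated call contracts
(:class:`ContractError`, CLI exit status 3).
"""


class ActikitError(Exception):
    """Base class for all actikit errors."""


class FormatError(ActikitError):
    """Input file or schema is malformed (bad header, non-numeric cell, ...)."""

    exit_code = 2


class ParseError(FormatError):
    """A specific cell or line could not be parsed; message carries its location."""


class ContractError(ActikitError):
    """A precondition or invariant of an operation was violated by the caller."""

    exit_code = 3
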