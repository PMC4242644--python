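"""Exception hierarchy shared across the package."""


class CoexMotifError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CoexMotifError):
    """A configuration value violates its documented constraints."""


class ParseError(CoexMotifError):
    """An input file could not be parsed; the message names the location."""


class DegenerateInputError(CoexMotifError):
    """An operation received input it cannot meaningfully process (e.g. empty)."""


class UnknownGeneError(CoexMotifError):
    """A referenced gene is absent from the structure being queried."""


class UnknownContigError(CoexMotifError):
    """A feature references a contig not present in the genome."""


class ContractError(CoexMotifError):
    """A caller violated an operation precondition."""
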