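"""Exception hierarchy for rapa."""


class RapaError(Exception):
    """Base class for all rapa errors."""


class ParseError(RapaError):
    """Input structure text could not be parsed."""


class EmptyStructureError(RapaError):
    """No protein residues remained after filtering."""


class IncompleteSideChainError(RapaError):
    """A residue is missing atoms required for state enumeration."""


class ContractError(RapaError):
    """An operation was called outside its preconditions."""


class ResourceLimitError(RapaError):
    """A combinatorial safety bound was exceeded."""


class ParameterError(RapaError):
    """A user-supplied parameter is outside its sanity bounds."""
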