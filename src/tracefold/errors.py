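"""Exception types shared across the package."""


class TracefoldError(Exception):
    """Base class for all package-specific errors."""


class InvalidStructureError(TracefoldError):
    """A base-pair set or chain violates a structural invariant."""


class ParseError(TracefoldError):
    """A text input (PDB, dot-bracket, contact table) could not be parsed."""


class EmptyChainError(ParseError):
    """A PDB input contained no phosphate atoms."""


class ConstructionError(TracefoldError):
    """A synthetic topology could not be built to its geometric tolerances."""
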