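"""Exception hierarchy shared across the package."""


class DTMNError(Exception):
    """Base class for all package errors."""


class DomainError(DTMNError, ValueError):
    """A value is outside the domain a contract requires (bad label index,
    invalid probability, malformed configuration)."""


class StructuralError(DTMNError, ValueError):
    """Input has the right kind but the wrong structure (missing rows,
    shape mismatch, misaligned sequences)."""


class ParseError(StructuralError):
    """A cell or field could not be parsed as the required type."""
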