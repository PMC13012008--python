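"""Exception hierarchy shared across the pipeline stages."""


class NapyError(Exception):
    """Base class for all errors raised by this package."""


class IdentifierError(NapyError):
    """Duplicate or malformed gene/sample identifiers."""


class MatrixParseError(NapyError):
    """Non-numeric or otherwise unparseable expression input."""


class DomainError(NapyError):
    """A value outside the mathematical domain of an operation."""


class InsufficientDataError(NapyError):
    """Too few samples/genes/events for the requested computation."""


class MissingGeneError(NapyError, KeyError):
    """A required gene identifier is absent from a matrix or parameter set."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return NapyError.__str__(self)


class ContractError(NapyError):
    """Caller violated an interface precondition (mismatched inputs etc.)."""


class CoverageError(NapyError):
    """Too few signature genes present in the expression matrix."""


class DegenerateTableError(NapyError):
    """A contingency table with a zero margin or other degeneracy."""


class ConvergenceError(NapyError):
    """An iterative fit failed to converge."""
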