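"""Named validation errors raised by input readers and pipeline stages."""


class ValidationError(ValueError):
    """Base class for all domcert input-validation failures."""


class NonSquareMatrixError(ValidationError):
    """Win/loss matrix body is not square."""


class IDMismatchError(ValidationError):
    """Row and column identifier sequences of a win/loss matrix differ."""


class DuplicateIDError(ValidationError):
    """Individual identifiers are not unique (or are empty)."""


class NonIntegerCountError(ValidationError):
    """A win/loss cell is not an integer."""


class NegativeCountError(ValidationError):
    """A win/loss cell or edge-list count is negative."""


class NonzeroDiagonalError(ValidationError):
    """The diagonal of a win/loss matrix contains a nonzero entry."""


class SelfInteractionError(ValidationError):
    """An edge-list row has winner == loser (self-interaction)."""


class MissingColumnError(ValidationError):
    """A required edge-list column is absent."""


class UnknownIndividualError(ValidationError):
    """An identifier does not occur in the network / matrix."""


class InvalidParameterError(ValidationError):
    """A numeric parameter is outside its documented range."""
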