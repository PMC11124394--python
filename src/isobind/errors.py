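"""Exception hierarchy for table parsing and validation."""


class IsobindError(Exception):
    """Base class for all package errors."""


class ParseError(IsobindError):
    """A delimited-text cell could not be parsed; message names the cell."""


class ValidationError(IsobindError):
    """A table or profile violates a structural invariant."""


class LabelError(IsobindError):
    """Row/column labels are inconsistent between two tables."""


class DegenerateFitError(IsobindError):
    """A regression cannot be fit (constant or collinear predictors)."""


class InsufficientDataError(IsobindError):
    """Too few usable observations for a reported fit."""
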