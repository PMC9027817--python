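"""Exception hierarchy for the boutline pipeline.

Every error raised by this package derives from :class:`BoutlineError` so
callers can catch pipeline failures without masking programming errors.
"""


class BoutlineError(Exception):
    """Base class for all boutline errors."""


class SchemaError(BoutlineError):
    """A CSV file is missing a required column or has an unusable header."""


class ValidationError(BoutlineError):
    """A row violates an invariant (e.g. stop <= start, non-numeric time).

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number in the source file (header = line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(BoutlineError):
    """Invalid configuration: overlapping periods, bad simulator parameters."""


class ContractError(BoutlineError):
    """An internal precondition was breached (unsorted input, non-positive gap
    after normalization); indicates a pipeline-ordering bug, not bad data."""


class InsufficientDataError(BoutlineError):
    """Too few observations for the requested fit or correlation."""


class DegenerateFitError(BoutlineError):
    """The mixture fit collapsed (vanishing variance or component weight)."""

    def __init__(self, message: str, parameter: str | None = None):
        self.parameter = parameter
        super().__init__(message)


class IntersectionNotFoundError(BoutlineError):
    """The weighted component densities do not cross between the two means."""


class DegenerateRegressionError(BoutlineError):
    """Regression predictor is constant; coefficients are not identifiable."""


class RosterLookupError(BoutlineError):
    """An animal referenced by an operation is absent from the roster."""
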