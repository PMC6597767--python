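"""Exception types shared across the package."""


class ThyrodoseError(Exception):
    """Base class for package errors."""


class DomainError(ThyrodoseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidityError(ThyrodoseError, ValueError):
    """A parameter set violates the positivity conditions of the FT4 solution.

    Carries the offending evaluation point(s) when known.
    """

    def __init__(self, message, points=None):
        super().__init__(message)
        self.points = points


class InsufficientDataError(ThyrodoseError, ValueError):
    """A patient series is too short for the requested operation."""


class ValidationError(ThyrodoseError, ValueError):
    """A data file or record violates the visit-table invariants."""
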