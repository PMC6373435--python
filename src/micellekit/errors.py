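"""Exception hierarchy.

Validation problems raise :class:`InvalidInputError`; numerical problems
(integration blow-up, failed fits, missing curve crossings) raise
subclasses of :class:`NumericalError` so callers — and the CLI exit-code
mapping — can tell the two apart.
"""


class MicelleKitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MicelleKitError, ValueError):
    """An argument violates a documented precondition."""


class PlacementError(MicelleKitError):
    """Molecules could not be placed in the box after bounded retries."""


class GROParseError(InvalidInputError):
    """Malformed GRO content; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NumericalError(MicelleKitError):
    """Base class for run-time numerical failures."""


class IntegrationError(NumericalError):
    """Non-finite coordinates appeared during dynamics; names the step."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite coordinates at integration step {step}")


class FitFailureError(NumericalError):
    """Nonlinear fit did not converge."""


class NoCrossingError(NumericalError):
    """The fitted free-fraction curve never falls to the 50% threshold."""


class NoIntersectionError(NumericalError):
    """The two fitted tension lines are parallel within tolerance."""
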