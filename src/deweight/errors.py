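"""Exception hierarchy shared across the package."""


class DeweightError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DeweightError):
    """A required column is missing or a column has the wrong type/levels."""


class ValidationError(DeweightError):
    """Input data violate a contract (missing values, empty groups, ...)."""


class PositivityError(DeweightError):
    """A propensity score of 0 or 1 was produced or implied.

    Raised instead of silently clipping: a subgroup with no minority (or no
    majority) subjects has no finite balancing weight.
    """


class SeparationError(DeweightError):
    """The logistic likelihood is monotone (perfect separation)."""


class ConvergenceError(DeweightError):
    """An iterative fit stopped without meeting its tolerance."""

    def __init__(self, message: str, residual_norm: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm
        self.iterations = iterations
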