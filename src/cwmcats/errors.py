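"""Exception hierarchy shared by all cwmcats modules."""


class CWMCatsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CWMCatsError):
    """A file does not have the expected CSV layout (missing columns, bad header)."""


class ValidationError(CWMCatsError):
    """Input values violate a documented invariant (sign, range, uniqueness)."""


class SpeciesLookupError(CWMCatsError, KeyError):
    """A species referenced by an abundance matrix has no trait record."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "species missing from trait table: " + ", ".join(map(str, self.missing))
        )


class DegenerateDesignError(CWMCatsError):
    """A model cannot be fit: zero-variance predictor or response, empty cell, rank deficiency."""


class InfeasibleConstraintError(CWMCatsError):
    """CWM constraint vector lies outside the convex hull of the species trait vectors.

    Carries the feasibility report so callers can inspect the hull
    projection and its distance.
    """

    def __init__(self, report):
        self.report = report
        super().__init__(
            f"constraint vector infeasible: distance to trait convex hull = "
            f"{report.distance:.6g} (standardized units); nearest attainable "
            f"constraints = {report.projected_constraints}"
        )


class ConvergenceError(CWMCatsError):
    """Iterative solver exhausted its iteration budget before meeting tolerance."""

    def __init__(self, message, residuals=None, iterations=None):
        self.residuals = residuals
        self.iterations = iterations
        super().__init__(message)


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the environmental range used for calibration."""
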