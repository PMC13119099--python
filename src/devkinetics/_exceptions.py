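"""Exception hierarchy shared across the package."""


class DevKineticsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DevKineticsError, ValueError):
    """A file does not conform to the expected column layout."""


class ValidationError(DevKineticsError, ValueError):
    """Input data violate a structural invariant (e.g. decreasing counts)."""


class EmptyCurveError(DevKineticsError, ValueError):
    """A treatment produced no survivors, so no normalized curve exists."""


class DegenerateCurveError(DevKineticsError, ValueError):
    """A curve carries no interior (0 < y < 1) information to fit."""


class FitConvergenceError(DevKineticsError, RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries the best iterate found so it can be inspected.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class ParallelLinesError(DevKineticsError, ValueError):
    """Two regression segments are parallel; no breakpoint exists."""
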