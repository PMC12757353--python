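"""Exception hierarchy shared across the package."""


class AllomixError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AllomixError, ValueError):
    """Input violates a documented precondition or invariant."""


class TreeTableFormatError(AllomixError, ValueError):
    """A tree table (CSV) is malformed: missing column, bad cell, etc."""


class DegenerateInputError(AllomixError, ValueError):
    """A statistic is undefined for this input (zero denominator etc.).

    Raised explicitly instead of silently returning NaN.
    """


class ConvergenceError(AllomixError, RuntimeError):
    """An iterative fit failed to converge.

    Carries the best parameters seen so far in ``best_params`` when
    available, so callers can inspect the trajectory.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params
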