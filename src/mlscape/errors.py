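"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MlscapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MlscapeError, ValueError):
    """A configuration object violates its invariants."""


class ShapeError(MlscapeError, ValueError):
    """Parameter or data dimensions are inconsistent."""


class EmptyCohortError(MlscapeError, ValueError):
    """No patients survive feature assembly for the requested item set."""


class DegenerateFeatureError(MlscapeError, ValueError):
    """A feature column cannot be scaled (zero mean)."""

    def __init__(self, column: str):
        super().__init__(f"column {column!r} has zero mean and cannot be scaled")
        self.column = column


class CannotSplitError(MlscapeError, ValueError):
    """Fewer than two patients: no train/test split exists."""


class DivergenceError(MlscapeError, RuntimeError):
    """The cost became non-finite during minimization."""


class NonConvergenceError(MlscapeError, RuntimeError):
    """Iteration cap reached before the gradient tolerance.

    Carries the best point found so callers can decide whether to retry.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class NotASaddleError(MlscapeError, RuntimeError):
    """Transition-state refinement converged to a point of Hessian index != 1."""

    def __init__(self, message: str, index: int | None = None, point=None):
        super().__init__(message)
        self.index = index
        self.point = point


class DisconnectedError(MlscapeError, ValueError):
    """The stationary-point database is not a single connected component."""

    def __init__(self, components):
        super().__init__(
            f"database has {len(components)} connected components: "
            + "; ".join(str(sorted(c)) for c in components)
        )
        self.components = components


class UndefinedROCError(MlscapeError, ValueError):
    """ROC analysis needs at least one patient in each outcome class."""


class UndefinedCorrelationError(MlscapeError, ValueError):
    """Correlation is undefined when either coordinate has zero variance."""
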