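"""Smooth cost-function oracles.

Everything downstream of the fitting functions — local minimization,
basin-hopping, transition-state searches, disconnectivity graphs — operates on
a :class:`CostOracle`: a bundle of value, gradient and (optionally) Hessian
callables over a flat parameter vector.  Both the classifier cost surfaces and
the analytic toy landscapes used as test fixtures implement this interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class CostOracle:
    """A smooth scalar function with analytic derivatives.

    Parameters
    ----------
    f : callable
        ``f(w) -> float`` cost value at the flat parameter vector ``w``.
    grad : callable
        ``grad(w) -> ndarray`` exact gradient, same shape as ``w``.
    hess : callable, optional
        ``hess(w) -> ndarray`` exact symmetric Hessian (dim x dim).
    dim : int
        Number of parameters.
    name : str
        Human-readable label used in logs and serialized databases.
    """

    f: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    dim: int
    hess: Callable[[np.ndarray], np.ndarray] | None = None
    name: str = "cost"

    def value_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        w = np.asarray(w, dtype=float)
        return float(self.f(w)), np.asarray(self.grad(w), dtype=float)

    def rms_grad(self, w: np.ndarray) -> float:
        """Root-mean-square gradient |g| / sqrt(dim)."""
        g = np.asarray(self.grad(w), dtype=float)
        return float(np.linalg.norm(g) / np.sqrt(self.dim))
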