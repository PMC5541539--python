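"""Shared fixtures: finite-difference oracles, small datasets, toy records."""

from __future__ import annotations

import numpy as np
import pytest

from mlscape import CohortSpec, PatientRecord, generate_cohort


def fd_gradient(f, w, h=1e-6):
    """Central finite-difference gradient (independent derivative oracle)."""
    w = np.asarray(w, dtype=float)
    g = np.zeros_like(w)
    for i in range(w.size):
        e = np.zeros_like(w)
        e[i] = h
        g[i] = (f(w + e) - f(w - e)) / (2 * h)
    return g


def fd_hessian(grad, w, h=1e-6):
    """Central finite differences of an analytic gradient."""
    w = np.asarray(w, dtype=float)
    n = w.size
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros_like(w)
        e[i] = h
        H[:, i] = (grad(w + e) - grad(w - e)) / (2 * h)
    return 0.5 * (H + H.T)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_data(rng):
    """Small positive-feature dataset with both outcome classes present."""
    X = rng.lognormal(mean=-0.125, sigma=0.5, size=(40, 3))
    c = rng.integers(0, 2, size=40)
    c[0], c[1] = 0, 1  # guarantee both classes
    return X, c


@pytest.fixture
def tiny_cohort():
    """Three hand-built patient records exercising the windowing edge cases."""
    return [
        PatientRecord("A", 0, [("HR", 47.5, 10.0), ("HR", 47.2, 20.0),
                               ("BUN", 0.5, 5.0)]),
        PatientRecord("B", 1, [("HR", 1.3, 7.0), ("BUN", 30.0, 3.0),
                               ("BUN", 46.4, 4.0)]),
        PatientRecord("C", 1, [("HR", 24.0, 9.0)]),  # BUN entirely missing
    ]


@pytest.fixture(scope="session")
def demo_spec():
    """A small synthetic cohort spec shared across pipeline tests."""
    return CohortSpec(
        n_patients=300,
        items=("HCO3", "GCS", "BUN"),
        effect_coeffs=(2.0, -1.5, 1.0),
        intercept=-2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_cohort(demo_spec):
    return generate_cohort(demo_spec)
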