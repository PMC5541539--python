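"""Synthetic patient cohorts with known ground truth.

The original study drew on a credentialed critical-care database: per patient,
irregularly timestamped vital-sign and laboratory measurements over a 48 h
window plus a binary outcome (0 = death in hospital, 1 = survival).  That data
cannot be redistributed, so this module generates cohorts with the same
*structure* — Poisson-timestamped measurements, item-wise missingness, a
33-item measurement panel if desired — from a latent logistic outcome model
whose Bayes-optimal discrimination is computable.  Every downstream stage
(windowing, scaling, fitting, ROC evaluation) can then be tested against a
known answer.

The module also hosts the analytic toy landscapes used to validate the
transition-state and disconnectivity machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InvalidSpecError
from .oracle import CostOracle

# Shape parameter of the unit-mean lognormal latent distribution.  sigma=0.5
# gives strictly positive, mildly right-skewed "physiological" values with
# mean exactly 1, so the pipeline's divide-by-mean scaling is near-identity.
LATENT_SIGMA = 0.5

#: Measurement panel mirroring the 33 vital-sign / laboratory item types of
#: the source clinical database (abbreviations as used in intensive care).
DEFAULT_ITEM_PANEL = (
    "HCT", "troponin", "cholesterol", "ALP", "FiO2", "PaO2", "PaCO2",
    "albumin", "ALT", "bilirubin", "lactate", "ADBP", "ASBP", "HCO3",
    "SpO2", "pH", "urine", "SaO2", "INR", "NIDBP", "NISBP", "Mg", "BUN",
    "creatinine", "TEMP", "GCS", "RR", "glucose", "Na", "K", "WBC",
    "platelets", "HR",
)

WINDOW_HOURS = 48.0


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a synthetic cohort.

    The outcome is Bernoulli with log-odds of class 0 (death) equal to
    ``intercept + sum(effect_coeffs * latent)`` where each per-patient latent
    item value is lognormal with unit mean.  Observed measurements are the
    latent value plus Gaussian noise at homogeneous-Poisson timestamps.
    """

    n_patients: int
    items: tuple[str, ...]
    effect_coeffs: tuple[float, ...]
    intercept: float = 0.0
    rate_per_item: float = 5.0
    missing_prob: float = 0.1
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if int(self.n_patients) < 1:
            raise InvalidSpecError(f"n_patients must be >= 1, got {self.n_patients}")
        if len(self.items) == 0:
            raise InvalidSpecError("items must be nonempty")
        if len(self.effect_coeffs) != len(self.items):
            raise InvalidSpecError(
                f"{len(self.effect_coeffs)} coefficients for {len(self.items)} items"
            )
        if self.rate_per_item < 0:
            raise InvalidSpecError("rate_per_item must be >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise InvalidSpecError("missing_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "effect_coeffs", tuple(float(c) for c in self.effect_coeffs))


@dataclass
class PatientRecord:
    """One patient: identifier, binary outcome, timestamped measurements.

    ``outcome`` is 0 for death in hospital and 1 for survival.  Each
    measurement is ``(item, time_h, value)`` with ``time_h`` in [0, 48) hours
    from the start of the observation window.
    """

    patient_id: str
    outcome: int
    measurements: list[tuple[str, float, float]] = field(default_factory=list)


def _draw_latents(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    # unit-mean lognormal: E[exp(N(mu, s^2))] = exp(mu + s^2/2) = 1
    mu = -0.5 * LATENT_SIGMA**2
    return rng.lognormal(mean=mu, sigma=LATENT_SIGMA, size=(n, len(spec.items)))


def _outcome_log_odds(spec: CohortSpec, latents: np.ndarray) -> np.ndarray:
    """Log-odds of class 0 (death) under the generating model."""
    coeffs = np.asarray(spec.effect_coeffs, dtype=float)
    return spec.intercept + latents @ coeffs


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort from ``spec``.

    Randomness flows from ``spec.seed`` through a single generator in a fixed
    draw order (latents, outcomes, missingness, then per-item timestamps and
    noise), so identical specs produce bitwise-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_patients)
    n_items = len(spec.items)

    latents = _draw_latents(spec, rng, n)
    p_death = expit(_outcome_log_odds(spec, latents))
    outcomes = np.where(rng.random(n) < p_death, 0, 1)
    missing = rng.random((n, n_items)) < spec.missing_prob

    records: list[PatientRecord] = []
    width = len(str(n - 1))
    for a in range(n):
        meas: list[tuple[str, float, float]] = []
        for k, item in enumerate(spec.items):
            if missing[a, k]:
                continue
            n_obs = rng.poisson(spec.rate_per_item)
            if n_obs == 0:
                continue
            times = rng.uniform(0.0, WINDOW_HOURS, size=n_obs)
            values = latents[a, k] + rng.normal(0.0, spec.noise_sd, size=n_obs)
            meas.extend((item, float(t), float(v)) for t, v in zip(times, values))
        records.append(
            PatientRecord(patient_id=f"P{a:0{width}d}", outcome=int(outcomes[a]), measurements=meas)
        )
    return records


def oracle_bayes_auc(spec: CohortSpec, n_mc: int) -> float:
    """Monte-Carlo AUC of the true generating log-odds used as risk score.

    This is the Bayes-optimal discrimination achievable on cohorts drawn from
    ``spec``: the probability that a randomly chosen class-0 (death) patient
    receives a higher true log-odds than a randomly chosen class-1 patient
    (ties counted half).  Fitted models cannot beat it in expectation, which
    makes it the recovery target for end-to-end tests.
    """
    if n_mc < 1:
        raise InvalidSpecError(f"n_mc must be >= 1, got {n_mc}")
    rng = np.random.default_rng([int(spec.seed), 0x0A1C])
    latents = _draw_latents(spec, rng, int(n_mc))
    score = _outcome_log_odds(spec, latents)
    outcome0 = rng.random(int(n_mc)) < expit(score)
    from .evaluate import mann_whitney_auc  # local import avoids a cycle

    return mann_whitney_auc(score, np.where(outcome0, 0, 1))


# ---------------------------------------------------------------------------
# Analytic toy landscapes


def _double_well() -> CostOracle:
    # f(w) = (w^2 - 1)^2: minima at w = +-1 (E=0), index-1 saddle at 0 (E=1)
    return CostOracle(
        f=lambda w: float((w[0] ** 2 - 1.0) ** 2),
        grad=lambda w: np.array([4.0 * w[0] * (w[0] ** 2 - 1.0)]),
        hess=lambda w: np.array([[12.0 * w[0] ** 2 - 4.0]]),
        dim=1,
        name="double_well",
    )


def _two_dim_double_well() -> CostOracle:
    # f(w1,w2) = (w1^2-1)^2 + w2^2: minima (+-1,0), saddle (0,0)
    return CostOracle(
        f=lambda w: float((w[0] ** 2 - 1.0) ** 2 + w[1] ** 2),
        grad=lambda w: np.array([4.0 * w[0] * (w[0] ** 2 - 1.0), 2.0 * w[1]]),
        hess=lambda w: np.array([[12.0 * w[0] ** 2 - 4.0, 0.0], [0.0, 2.0]]),
        dim=2,
        name="two_dim_double_well",
    )


def _three_well() -> CostOracle:
    # f(w) = w^2 (w^2 - 1)^2: three degenerate minima at 0, +-1 (E=0) and
    # two saddles at +-1/sqrt(3) with E = 4/27
    return CostOracle(
        f=lambda w: float(w[0] ** 2 * (w[0] ** 2 - 1.0) ** 2),
        grad=lambda w: np.array([6.0 * w[0] ** 5 - 8.0 * w[0] ** 3 + 2.0 * w[0]]),
        hess=lambda w: np.array([[30.0 * w[0] ** 4 - 24.0 * w[0] ** 2 + 2.0]]),
        dim=1,
        name="three_well",
    )


_TOY_LANDSCAPES = {
    "double_well": _double_well,
    "two_dim_double_well": _two_dim_double_well,
    "three_well": _three_well,
}


def toy_landscape(name: str) -> CostOracle:
    """Return a named analytic landscape with exact derivatives.

    Available fixtures: ``double_well`` ((w^2-1)^2), ``two_dim_double_well``
    ((w1^2-1)^2 + w2^2) and ``three_well`` (w^2 (w^2-1)^2, three degenerate
    minima).  These exercise the minimization, saddle-search and
    disconnectivity machinery against closed-form stationary points.
    """
    try:
        factory = _TOY_LANDSCAPES[name]
    except KeyError:
        raise KeyError(
            f"unknown toy landscape {name!r}; available: {sorted(_TOY_LANDSCAPES)}"
        ) from None
    return factory()
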