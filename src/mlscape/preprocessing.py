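"""From irregular timestamped cohorts to fixed-size scaled feature matrices.

The observation window is 48 h of hospitalization.  Hourly windows are
indexed *backwards in time*: window 1 is the most recent hour, window 48 the
earliest.  Measurements of each item are averaged within each hourly window;
empty windows are filled from the chronologically earliest non-zero hourly
average; a feature is then the mean of the filled windows over a requested
hour range (e.g. 1, 1-2, 1-6).  Each feature column is divided by its mean
over all patients so every input has unit mean ("feature scaling"), and
patients are split at random into equally sized training and testing halves
(the extra patient goes to testing when the count is odd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import PatientRecord, WINDOW_HOURS
from .errors import (
    CannotSplitError,
    DegenerateFeatureError,
    EmptyCohortError,
    InvalidSpecError,
)

logger = logging.getLogger(__name__)

N_WINDOWS = 48


@dataclass(frozen=True)
class TimeRange:
    """Inclusive range of hourly windows, hour 1 = most recent."""

    first_hour: int
    last_hour: int

    def __post_init__(self):
        if not (1 <= self.first_hour <= self.last_hour <= N_WINDOWS):
            raise InvalidSpecError(
                f"need 1 <= first_hour <= last_hour <= {N_WINDOWS}, "
                f"got {self.first_hour}-{self.last_hour}"
            )

    @property
    def label(self) -> str:
        if self.first_hour == self.last_hour:
            return str(self.first_hour)
        return f"{self.first_hour}-{self.last_hour}"

    @classmethod
    def parse(cls, text: str) -> "TimeRange":
        parts = str(text).split("-")
        if len(parts) == 1:
            h = int(parts[0])
            return cls(h, h)
        return cls(int(parts[0]), int(parts[1]))


@dataclass
class FeatureMatrix:
    """Scaled per-patient inputs plus binary outcomes.

    ``X`` is (N_data, N_in); ``outcomes`` holds the class labels (0 = death,
    1 = survival); ``item_labels`` names each column (item plus time-range
    tag); ``scale_means`` records the per-column means divided out by
    :func:`scale_features` (``None`` while unscaled).
    """

    X: np.ndarray
    outcomes: np.ndarray
    item_labels: list[str]
    patient_ids: list[str]
    scale_means: np.ndarray | None = None

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_in(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[idx].copy(),
            outcomes=self.outcomes[idx].copy(),
            item_labels=list(self.item_labels),
            patient_ids=[self.patient_ids[i] for i in idx],
            scale_means=None if self.scale_means is None else self.scale_means.copy(),
        )


def hourly_bin(record: PatientRecord, item: str) -> np.ndarray:
    """Average an item's measurements into the 48 backward-indexed windows.

    Window ``i`` covers ``(48-i, 48-i+1]`` hours from the window start, so a
    timestamp at 47.5 h lands in window 1 (most recent) and one at 0.5 h in
    window 48.  A timestamp of exactly 0.0 — allowed by the [0, 48) contract
    but on no half-open boundary — is assigned to window 48.  Windows with no
    measurements are NaN.  An item absent from the record yields an all-NaN
    vector (logged, not an error).
    """
    sums = np.zeros(N_WINDOWS)
    counts = np.zeros(N_WINDOWS, dtype=int)
    seen = False
    for name, t, v in record.measurements:
        if name != item:
            continue
        seen = True
        if not 0.0 <= t < WINDOW_HOURS:
            raise InvalidSpecError(f"measurement time {t} outside [0, 48)")
        # window index i solves 48-i < t <= 48-i+1, i.e. i = floor(48-t) + 1;
        # a timestamp exactly at 48-i lands in window i+1 by the half-open rule
        i = int(np.floor(WINDOW_HOURS - t)) + 1
        i = min(max(i, 1), N_WINDOWS)  # t == 0.0 folds into window 48
        sums[i - 1] += v
        counts[i - 1] += 1
    if not seen:
        logger.debug("item %r has no measurements for patient %s", item, record.patient_id)
    out = np.full(N_WINDOWS, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def fill_missing(binned: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fill empty windows from the earliest non-zero hourly average.

    "Earliest" is chronological, i.e. the *largest* window index (window 48
    is the start of the 48 h record).  Returns ``(filled, all_missing)``;
    when no non-empty, non-zero window exists the vector is returned as-is
    and flagged all-missing.
    """
    binned = np.asarray(binned, dtype=float)
    if binned.shape != (N_WINDOWS,):
        raise InvalidSpecError(f"expected a 48-vector, got shape {binned.shape}")
    fill_value = None
    for i in range(N_WINDOWS - 1, -1, -1):  # largest index first
        if np.isfinite(binned[i]) and binned[i] != 0.0:
            fill_value = binned[i]
            break
    if fill_value is None:
        return binned.copy(), True
    out = binned.copy()
    out[~np.isfinite(out)] = fill_value
    return out, False


def assemble_features(
    cohort: list[PatientRecord],
    items: list[str],
    time_range: TimeRange,
) -> FeatureMatrix:
    """Build the (unscaled) feature matrix for an item set and hour range.

    One column per item: the mean of the filled hourly averages over hours
    ``first_hour..last_hour``.  Patients for whom any requested item is
    entirely missing are excluded — this is why the usable patient count
    varies with the item combination.
    """
    if not items:
        raise InvalidSpecError("items must be nonempty")
    lo, hi = time_range.first_hour - 1, time_range.last_hour  # slice bounds
    rows, labels_c, ids = [], None, []
    outcomes = []
    for rec in cohort:
        if rec.outcome not in (0, 1):
            raise InvalidSpecError(f"outcome {rec.outcome!r} for {rec.patient_id}")
        feats = np.empty(len(items))
        ok = True
        for k, item in enumerate(items):
            filled, all_missing = fill_missing(hourly_bin(rec, item))
            if all_missing:
                ok = False
                break
            feats[k] = float(np.mean(filled[lo:hi]))
        if ok:
            rows.append(feats)
            ids.append(rec.patient_id)
            outcomes.append(rec.outcome)
    if not rows:
        raise EmptyCohortError(
            f"no patients have complete data for items {items} in range {time_range.label}"
        )
    return FeatureMatrix(
        X=np.array(rows),
        outcomes=np.array(outcomes, dtype=int),
        item_labels=[f"{item}[{time_range.label}]" for item in items],
        patient_ids=ids,
        scale_means=None,
    )


def drop_contradictory(records: list[PatientRecord],
                       contradictory_ids: set[str]) -> list[PatientRecord]:
    """Remove records whose reported outcomes conflict (death *and* discharge)."""
    return [r for r in records if r.patient_id not in contradictory_ids]


def scale_features(m: FeatureMatrix) -> FeatureMatrix:
    """Divide each column by its mean over all patients (mean shifts to 1).

    The means are computed over the full population in ``m`` — train and test
    together when called before splitting, which mirrors the per-item
    all-patient averages of the original pipeline and is a mild, documented
    information leak.  Idempotent: rescaling a scaled matrix is the identity.
    """
    means = m.X.mean(axis=0)
    for j, mu in enumerate(means):
        if mu == 0.0 or not np.isfinite(mu):
            raise DegenerateFeatureError(m.item_labels[j])
    return FeatureMatrix(
        X=m.X / means,
        outcomes=m.outcomes.copy(),
        item_labels=list(m.item_labels),
        patient_ids=list(m.patient_ids),
        scale_means=means.copy(),
    )


def split_train_test(m: FeatureMatrix, seed: int) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Random disjoint halves; testing gets the extra patient when N is odd."""
    n = m.n_patients
    if n < 2:
        raise CannotSplitError(f"cannot split {n} patient(s)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = n // 2
    return m.subset(np.sort(perm[:n_train])), m.subset(np.sort(perm[n_train:]))
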