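r"""ROC/AUC evaluation, sweep enumeration and repeat statistics.

The positive class throughout is outcome 0 (death in hospital): the true
positive rate at threshold ``P`` is the fraction of class-0 patients whose
predicted death probability ``p_0`` satisfies ``p_0 >= P``, and the false
positive rate the analogous fraction of class-1 patients.  The area under the
ROC curve is the trapezoidal integral :math:`\int T_{pr}\, dF_{pr}`, which
equals the probability that a random class-0 patient outscores a random
class-1 patient (ties counted half) — the Mann-Whitney statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidSpecError, UndefinedCorrelationError, UndefinedROCError
from .preprocessing import FeatureMatrix, TimeRange, split_train_test


@dataclass
class ROCCurve:
    """Thresholds (descending), (F_pr, T_pr) points and the integrated AUC."""

    thresholds: np.ndarray
    points: np.ndarray  # (n, 2) columns (F_pr, T_pr)
    auc: float


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int).ravel()
    pos = labels == 0
    neg = labels == 1
    if not pos.any() or not neg.any():
        raise UndefinedROCError("ROC requires at least one patient of each outcome")
    return pos, neg


def roc_curve(p0: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve of the death probability ``p0`` against outcomes.

    Thresholds are the descending unique scores plus a sentinel above the
    maximum, so the curve is anchored at (0, 0) and ends at (1, 1).  Scores
    exactly at the threshold count as predicted positive.
    """
    p0 = np.asarray(p0, dtype=float).ravel()
    pos, neg = _check_classes(labels)
    if p0.shape[0] != pos.shape[0]:
        raise InvalidSpecError("scores and labels differ in length")
    uniq = np.unique(p0)[::-1]
    thresholds = np.concatenate([[uniq[0] + 1.0], uniq])
    tpr = np.array([(p0[pos] >= P).mean() for P in thresholds])
    fpr = np.array([(p0[neg] >= P).mean() for P in thresholds])
    points = np.column_stack([fpr, tpr])
    return ROCCurve(thresholds=thresholds, points=points,
                    auc=float(np.trapezoid(tpr, fpr)))


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve's (F_pr, T_pr) points."""
    return float(np.trapezoid(curve.points[:, 1], curve.points[:, 0]))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-ordering AUC: P(score_pos > score_neg) + half the ties.

    Rank-based O(n log n) evaluation; exactly equals the trapezoidal ROC
    area.  Positive class is outcome 0.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    pos, neg = _check_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(scores)  # average ranks handle ties
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def best_auc_over_minima(db, test: FeatureMatrix, model) -> tuple[float, int]:
    """Best test AUC over every stored minimum, and which minimum attains it.

    ``model`` is a cost object exposing ``predict_p0(W, X)`` (the training
    fit bound to its architecture); each minimum's weights are evaluated on
    the held-out patients.  Different local minima of the training cost can
    generalize differently, so the survey keeps them all.
    """
    if len(db) == 0:
        raise InvalidSpecError("empty minima database")
    best, best_i = -np.inf, -1
    for i, m in enumerate(db):
        a = mann_whitney_auc(model.predict_p0(m.W, test.X), test.outcomes)
        if a > best:
            best, best_i = a, i
    return float(best), best_i


# ---------------------------------------------------------------------------
# Sweep enumeration


@dataclass(frozen=True)
class RunDescriptor:
    """One global-optimization run: inputs, window, architecture, ridge."""

    items: tuple[str, ...]
    time_range: TimeRange
    n_hidden: int | None  # None for the quadratic fit
    lam: float


@dataclass
class SweepSpec:
    """Cartesian experiment design over item combinations and settings.

    ``hidden_nodes`` empty means quadratic fits (a single architecture).
    ``exclusions`` lists (time_range, n_hidden) cells to skip, e.g. the
    longest window dropped for the largest network.
    """

    item_panel: tuple[str, ...]
    combo_size: int
    time_ranges: tuple[TimeRange, ...]
    hidden_nodes: tuple[int, ...] = ()
    lambdas: tuple[float, ...] = (1e-5,)
    exclusions: tuple[tuple[TimeRange, int], ...] = ()

    def __post_init__(self):
        if not 1 <= self.combo_size <= len(self.item_panel):
            raise InvalidSpecError("combo_size must be in [1, panel size]")


def enumerate_runs(spec: SweepSpec) -> list[RunDescriptor]:
    """All runs of the design in lexicographic order.

    Order: item combinations (panel order), then time ranges, hidden-node
    counts and lambdas as given, minus the excluded (range, hidden) cells.
    """
    hidden: tuple[int | None, ...] = spec.hidden_nodes or (None,)
    excl = set((tr, h) for tr, h in spec.exclusions)
    runs = []
    for combo in itertools.combinations(spec.item_panel, spec.combo_size):
        for tr in spec.time_ranges:
            for h in hidden:
                if (tr, h) in excl:
                    continue
                for lam in spec.lambdas:
                    runs.append(RunDescriptor(items=combo, time_range=tr,
                                              n_hidden=h, lam=lam))
    return runs


@dataclass
class SweepResult:
    """Outcome of one run of the sweep harness."""

    items: tuple[str, ...]
    time_range: TimeRange
    n_hidden: int | None
    lam: float
    best_test_auc: float
    best_test_E: float
    n_train: int
    n_test: int
    n_minima: int


# ---------------------------------------------------------------------------
# Repeat-randomization statistics and model agreement


def repeat_stats(fit_fn, fm: FeatureMatrix, seeds: list[int]) -> tuple[float, float]:
    """Mean and sample SD of the best test AUC over re-randomized splits.

    For each seed the patients are re-divided into training and testing
    halves, ``fit_fn(train, seed) -> model_with_db`` refits from scratch (the
    optimizer seed is re-randomized along with the split), and the best test
    AUC over the resulting minima is recorded.  SD uses the n-1 denominator.
    """
    if len(seeds) < 2:
        raise InvalidSpecError("repeat statistics need at least 2 repeats")
    aucs = []
    for seed in seeds:
        train, test = split_train_test(fm, seed)
        model, db = fit_fn(train, seed)
        best, _ = best_auc_over_minima(db, test, model)
        aucs.append(best)
    a = np.asarray(aucs)
    return float(a.mean()), float(a.std(ddof=1))


def model_correlation(pairs) -> tuple[float, float, float]:
    """Pearson correlation (and regression line) of paired best AUC values.

    ``pairs`` is a sequence of (nn_auc, quadratic_auc).  Returns
    ``(r, slope, intercept)`` of the least-squares regression of the network
    values on the quadratic values.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidSpecError("need at least 3 (nn, quadratic) pairs")
    qx, ny = arr[:, 1], arr[:, 0]
    if np.allclose(qx, qx[0]) or np.allclose(ny, ny[0]):
        raise UndefinedCorrelationError("zero variance in one coordinate")
    res = stats.linregress(qx, ny)
    return float(res.rvalue), float(res.slope), float(res.intercept)
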