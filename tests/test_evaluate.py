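"""ROC/AUC semantics, sweep enumeration, repeat statistics, model agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from mlscape import (
    FeatureMatrix,
    MinimaDatabase,
    Minimum,
    SweepSpec,
    TimeRange,
    auc,
    best_auc_over_minima,
    enumerate_runs,
    mann_whitney_auc,
    model_correlation,
    repeat_stats,
    roc_curve,
)
from mlscape.errors import (
    InvalidSpecError,
    UndefinedCorrelationError,
    UndefinedROCError,
)


def brute_force_auc(scores, labels):
    """O(n^2) pairwise oracle: correct orderings plus half the ties."""
    pos = [s for s, l in zip(scores, labels) if l == 0]
    neg = [s for s, l in zip(scores, labels) if l == 1]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ranking(self):
        c = roc_curve(np.array([0.9, 0.4]), np.array([0, 1]))
        assert [tuple(p) for p in c.points] == [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        assert c.auc == 1.0

    def test_constant_scores_give_chance(self):
        c = roc_curve(np.array([0.5, 0.5, 0.5, 0.5]), np.array([0, 1, 0, 1]))
        assert [tuple(p) for p in c.points] == [(0.0, 0.0), (1.0, 1.0)]
        assert c.auc == 0.5

    def test_reversed_scores_complement_auc(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedROCError):
            roc_curve(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_curve_monotone_and_anchored(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        c = roc_curve(scores, labels)
        assert tuple(c.points[0]) == (0.0, 0.0)
        assert tuple(c.points[-1]) == (1.0, 1.0)
        assert (np.diff(c.points[:, 0]) >= 0).all()
        assert (np.diff(c.points[:, 1]) >= 0).all()
        assert (np.diff(c.thresholds) <= 0).all()


class TestAUC:
    def test_worked_example(self):
        # positives 0.9, 0.4 vs negatives 0.6, 0.1: 3 of 4 pairs ordered
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([0, 0, 1, 1])
        assert auc(roc_curve(scores, labels)) == pytest.approx(0.75, abs=1e-12)
        assert mann_whitney_auc(scores, labels) == pytest.approx(0.75, abs=1e-12)

    def test_separated_scores_give_one(self):
        assert mann_whitney_auc(np.array([3.0, 2.0, 1.0, 0.0]),
                                np.array([0, 0, 1, 1])) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(1000)
        labels = np.repeat([0, 1], 500)
        se = np.sqrt(1 / 12 * (1 / 500 + 1 / 500))  # Mann-Whitney normal approx
        assert abs(mann_whitney_auc(scores, labels) - 0.5) < 3 * se

    @pytest.mark.parametrize("trial", range(20))
    def test_trapezoid_equals_pairwise_statistic(self, trial):
        # ties included by drawing from a coarse grid
        rng = np.random.default_rng(3000 + trial)
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 6, n) / 5.0
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        trap = auc(roc_curve(scores, labels))
        pair = mann_whitney_auc(scores, labels)
        assert trap == pytest.approx(pair, abs=1e-12)
        assert pair == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        # sklearn cross-check (its positive class is label 1, ours is 0)
        assert pair == pytest.approx(roc_auc_score(1 - labels, scores), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        base = mann_whitney_auc(scores, labels)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert mann_whitney_auc(f(scores), labels) == pytest.approx(base, abs=1e-12)


class _ScoreModel:
    """Stub fitting function scoring patients by a fixed rule."""

    def __init__(self, rule):
        self.rule = rule

    def predict_p0(self, w, X):
        return self.rule(X)


class TestBestOverMinima:
    def _fm(self, rng, n=30):
        X = rng.normal(size=(n, 2))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        return FeatureMatrix(X=X, outcomes=labels,
                             item_labels=["a[1]", "b[1]"],
                             patient_ids=[str(i) for i in range(n)])

    def _db(self, k):
        db = MinimaDatabase()
        for i in range(k):
            db.add(Minimum(W=np.array([float(i)]), E=float(i), rms_grad=0.0, n_iter=0))
        return db

    def test_singleton_database(self, rng):
        fm = self._fm(rng)
        model = _ScoreModel(lambda X: X[:, 0])
        best, idx = best_auc_over_minima(self._db(1), fm, model)
        assert idx == 0
        assert best == pytest.approx(mann_whitney_auc(fm.X[:, 0], fm.outcomes))

    def test_equals_brute_force_max(self, rng):
        fm = self._fm(rng)
        model = _ScoreModel(lambda X, w=[0]: X[:, 0] * (1 + w[0]))

        class PerMin:
            def predict_p0(self, w, X):
                return X[:, 0] * w[0] + X[:, 1] * (1 - w[0])

        db = self._db(3)
        best, idx = best_auc_over_minima(db, fm, PerMin())
        all_aucs = [
            mann_whitney_auc(PerMin().predict_p0(m.W, fm.X), fm.outcomes) for m in db
        ]
        assert best == max(all_aucs)
        assert idx == int(np.argmax(all_aucs))
        assert best >= all_aucs[0]  # dominates the training global minimum

    def test_empty_database_rejected(self, rng):
        with pytest.raises(InvalidSpecError):
            best_auc_over_minima(MinimaDatabase(), self._fm(rng), _ScoreModel(None))


def tr(text):
    return TimeRange.parse(text)


class TestEnumerateRuns:
    def test_pair_survey_counts(self):
        # 22-item panel, all pairs, 5 windows, 3 architectures
        spec = SweepSpec(
            item_panel=tuple(f"m{i}" for i in range(22)), combo_size=2,
            time_ranges=(tr("1"), tr("1-2"), tr("1-3"), tr("1-6"), tr("1-12")),
            hidden_nodes=(3, 5, 7),
        )
        runs = enumerate_runs(spec)
        assert len({r.items for r in runs}) == 231
        assert len(runs) == 3465

    def test_triplet_survey_counts(self):
        spec = SweepSpec(
            item_panel=tuple(f"m{i}" for i in range(22)), combo_size=3,
            time_ranges=(tr("1"), tr("1-2")), hidden_nodes=(3, 5),
        )
        runs = enumerate_runs(spec)
        assert len({r.items for r in runs}) == 1540
        assert len(runs) == 6160

    def test_quartet_survey_counts(self):
        spec = SweepSpec(
            item_panel=tuple(f"m{i}" for i in range(14)), combo_size=4,
            time_ranges=(tr("1"), tr("1-2")), hidden_nodes=(3, 5, 7),
        )
        runs = enumerate_runs(spec)
        assert len({r.items for r in runs}) == 1001
        assert len(runs) == 6006

    def test_singleton_everything(self):
        spec = SweepSpec(item_panel=("a",), combo_size=1, time_ranges=(tr("1"),))
        assert len(enumerate_runs(spec)) == 1

    def test_quadratic_panel_has_single_architecture(self):
        spec = SweepSpec(item_panel=("a", "b"), combo_size=2,
                         time_ranges=(tr("1"), tr("1-2")))
        runs = enumerate_runs(spec)
        assert len(runs) == 2
        assert all(r.n_hidden is None for r in runs)

    @given(
        n_items=st.integers(2, 8), combo=st.integers(1, 3),
        n_ranges=st.integers(1, 4), n_hidden=st.integers(0, 3),
        n_lam=st.integers(1, 2), n_excl=st.integers(0, 3),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_matches_closed_form(self, n_items, combo, n_ranges,
                                       n_hidden, n_lam, n_excl):
        combo = min(combo, n_items)
        ranges = tuple(TimeRange(1, 1 + i) for i in range(n_ranges))
        hidden = tuple(range(3, 3 + n_hidden))
        cells = [(t, h) for t in ranges for h in (hidden or (None,))]
        excl = tuple(cells[:min(n_excl, len(cells) - 1)])
        spec = SweepSpec(
            item_panel=tuple(f"i{k}" for k in range(n_items)), combo_size=combo,
            time_ranges=ranges, hidden_nodes=hidden,
            lambdas=tuple(10.0 ** -(5 + i) for i in range(n_lam)),
            exclusions=excl,
        )
        from math import comb
        expected = comb(n_items, combo) * (len(cells) - len(excl)) * n_lam
        assert len(enumerate_runs(spec)) == expected


class TestRepeatStats:
    def _fm(self, n=40):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, 1))
        labels = np.tile([0, 1], n // 2)
        return FeatureMatrix(X=X, outcomes=labels, item_labels=["a[1]"],
                             patient_ids=[str(i) for i in range(n)])

    def test_identical_repeats_have_zero_sd(self):
        fm = self._fm()

        def fit_fn(train, seed):  # all ties every repeat: AUC exactly 1/2
            db = MinimaDatabase()
            db.add(Minimum(W=np.zeros(1), E=0.0, rms_grad=0.0, n_iter=0))
            return _ScoreModel(lambda X: np.zeros(X.shape[0])), db

        mean, sd = repeat_stats(fit_fn, fm, seeds=[1, 2, 3])
        assert mean == 0.5 and sd == 0.0

    def test_two_known_values_closed_form(self):
        # seed-dependent stub: perfect ranking vs all ties -> AUCs 1.0 and 0.5
        fm = self._fm()

        def fit_fn(train, seed):
            db = MinimaDatabase()
            db.add(Minimum(W=np.zeros(1), E=0.0, rms_grad=0.0, n_iter=0))
            if seed == 1:
                return _ScoreModel(lambda X: np.zeros(X.shape[0])), db
            return _ScoreModel(lambda X: -X[:, 0]), db

        # make ranking perfect for the "good" seed by construction
        fm.X[:, 0] = fm.outcomes.astype(float)  # score -outcome ranks deaths first
        mean, sd = repeat_stats(fit_fn, fm, seeds=[1, 2])
        assert mean == pytest.approx(0.75, abs=1e-12)
        assert sd == pytest.approx(abs(1.0 - 0.5) / np.sqrt(2), abs=1e-12)

    def test_fewer_than_two_repeats_rejected(self):
        with pytest.raises(InvalidSpecError):
            repeat_stats(lambda *a: None, self._fm(), seeds=[1])

    def test_sd_shrinks_with_cohort_size(self):
        # synthetic latent-logistic features; quadratic refits per repeat
        from mlscape.pipeline import fit as pipeline_fit
        from scipy.special import expit

        def make_fm(n, seed):
            rng = np.random.default_rng(seed)
            X = rng.lognormal(mean=-0.125, sigma=0.5, size=(n, 2))
            logit0 = -1.0 + X @ np.array([2.0, -1.5])
            labels = np.where(rng.random(n) < expit(logit0), 0, 1)
            return FeatureMatrix(X=X, outcomes=labels,
                                 item_labels=["a[1]", "b[1]"],
                                 patient_ids=[str(i) for i in range(n)])

        def fit_fn(train, seed):
            return pipeline_fit(train, None, 1e-5, bh_steps=0, seed=seed)

        sds = {n: [] for n in (300, 3000)}
        for s in range(3):
            for n in sds:
                fm = make_fm(n, 50 + s)
                _, sd = repeat_stats(fit_fn, fm, seeds=[3 * s, 3 * s + 1, 3 * s + 2])
                sds[n].append(sd)
        assert np.median(sds[3000]) < np.median(sds[300])


class TestModelCorrelation:
    def test_collinear(self):
        pairs = [(0.1 + 0.5 * q, q) for q in (0.2, 0.4, 0.6, 0.8)]
        r, slope, intercept = model_correlation(pairs)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert intercept == pytest.approx(0.1, abs=1e-12)

    def test_anti_collinear(self):
        pairs = [(1.0 - q, q) for q in (0.2, 0.4, 0.6)]
        r, _, _ = model_correlation(pairs)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_pearson_formula(self):
        pairs = [(0.81, 0.78), (0.75, 0.70), (0.83, 0.85), (0.66, 0.60), (0.72, 0.74)]
        nn = np.array([p[0] for p in pairs])
        q = np.array([p[1] for p in pairs])
        hand = (np.sum((nn - nn.mean()) * (q - q.mean()))
                / np.sqrt(np.sum((nn - nn.mean()) ** 2) * np.sum((q - q.mean()) ** 2)))
        r, _, _ = model_correlation(pairs)
        assert r == pytest.approx(hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            model_correlation([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidSpecError):
            model_correlation([(0.1, 0.2), (0.3, 0.4)])
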