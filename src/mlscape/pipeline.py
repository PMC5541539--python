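"""End-to-end fitting pipeline: features -> basin-hopping fit -> test AUC.

Thin composition layer over the preprocessing, models, optimize and evaluate
modules; the sweep harness, the command-line interface and the examples all
go through these functions so a "run" means the same thing everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PatientRecord
from .evaluate import (
    RunDescriptor,
    SweepResult,
    SweepSpec,
    best_auc_over_minima,
    enumerate_runs,
)
from .models import NeuralNetCost, NNShape, QuadraticCost
from .optimize import BasinHopConfig, MinimaDatabase, basin_hop, minimize, random_params
from .preprocessing import (
    FeatureMatrix,
    TimeRange,
    assemble_features,
    scale_features,
    split_train_test,
)


def build_model(train: FeatureMatrix, n_hidden: int | None, lam: float):
    """Instantiate the training cost for a run descriptor's architecture."""
    if n_hidden is None:
        return QuadraticCost(train.n_in, train.X, train.outcomes, lam)
    shape = NNShape(n_in=train.n_in, n_hidden=n_hidden)
    return NeuralNetCost(shape, train.X, train.outcomes, lam)


def fit(train: FeatureMatrix, n_hidden: int | None, lam: float,
        bh_steps: int, seed: int,
        step_size: float = 1.0, temperature: float = 1.0):
    """Fit one model by basin-hopping; returns ``(cost_model, minima_db)``.

    ``bh_steps = 0`` performs a single tight local minimization from random
    weights — sufficient for the convex quadratic cost, whose database can
    never hold more than one minimum anyway.
    """
    model = build_model(train, n_hidden, lam)
    oracle = model.as_oracle()
    if bh_steps == 0:
        rng = np.random.default_rng(seed)
        m = minimize(oracle, random_params(oracle.dim, rng), tol=1e-10)
        db = MinimaDatabase()
        db.add(m)
        return model, db
    config = BasinHopConfig(n_steps=bh_steps, seed=seed,
                            step_size=step_size, temperature=temperature)
    db = basin_hop(oracle, None, config)
    return model, db


def run_one(cohort: list[PatientRecord], run: RunDescriptor,
            bh_steps: int, seed: int) -> SweepResult:
    """Assemble, scale, split, fit and evaluate a single run descriptor."""
    fm = scale_features(assemble_features(cohort, list(run.items), run.time_range))
    train, test = split_train_test(fm, seed)
    model, db = fit(train, run.n_hidden, run.lam, bh_steps, seed)
    best, best_i = best_auc_over_minima(db, test, model)
    test_model = build_model(test, run.n_hidden, run.lam)
    return SweepResult(
        items=run.items,
        time_range=run.time_range,
        n_hidden=run.n_hidden,
        lam=run.lam,
        best_test_auc=best,
        best_test_E=float(test_model.value(db[best_i].W)),
        n_train=train.n_patients,
        n_test=test.n_patients,
        n_minima=len(db),
    )


def run_sweep(cohort: list[PatientRecord], spec: SweepSpec,
              bh_steps: int, seed: int) -> list[SweepResult]:
    """Execute every run in the sweep design, in enumeration order.

    Each run derives its own split/optimizer seed deterministically from the
    sweep seed and its position, so results are reproducible run by run.
    """
    results = []
    for k, run in enumerate(enumerate_runs(spec)):
        run_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        results.append(run_one(cohort, run, bh_steps, run_seed))
    return results


def sweep_results_tsv(results: list[SweepResult], path) -> None:
    """Write sweep results as a TSV mirroring the survey-table layout."""
    with open(path, "w") as fh:
        fh.write("items\ttime\tN_h\tlambda\tAUC\ttest_E\tn_train\tn_test\tn_minima\n")
        for r in results:
            fh.write(
                " ".join(r.items) + "\t" + r.time_range.label + "\t"
                + ("Q" if r.n_hidden is None else str(r.n_hidden)) + "\t"
                + f"{r.lam:g}\t{r.best_test_auc:.6f}\t{r.best_test_E:.10g}\t"
                + f"{r.n_train}\t{r.n_test}\t{r.n_minima}\n"
            )
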