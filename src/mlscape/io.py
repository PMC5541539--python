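"""Plain-text serialization for every pipeline artifact.

All numeric round-trips use 17 significant digits (``%.17g``), which is
lossless for IEEE doubles, so a written-and-reread database reproduces the
in-memory values bitwise.  Formats:

* cohorts: two CSVs, ``measurements.csv`` (patient_id,item,time_h,value) and
  ``outcomes.csv`` (patient_id,outcome), UTF-8, '.' decimal;
* feature matrices: a TSV of patient rows plus a JSON sidecar holding the
  column labels, scaling means and split seed;
* parameter vectors: a ``#``-header (model kind and shape) then one value per
  line;
* minima databases: an index file (one line per minimum: E, rms_grad,
  n_iter, offset) and a weights file of flattened vectors, where ``offset``
  is the first line of the minimum's block in the weights file;
* transition states: an index file (E, neg_eigenvalue, min1, min2, offset)
  plus a weights file holding, per state, the point followed by its downhill
  eigenvector (2 x dim lines per block).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .landscape import StationaryPointDatabase, TransitionState
from .optimize import MinimaDatabase, Minimum
from .preprocessing import FeatureMatrix

G17 = "%.17g"


def _fmt(x: float) -> str:
    return G17 % x


# ---------------------------------------------------------------------------
# Cohorts


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        (r.patient_id, item, _fmt(t), _fmt(v))
        for r in records
        for item, t, v in r.measurements
    ]
    pd.DataFrame(rows, columns=["patient_id", "item", "time_h", "value"]).to_csv(
        out / "measurements.csv", index=False
    )
    pd.DataFrame(
        [(r.patient_id, r.outcome) for r in records],
        columns=["patient_id", "outcome"],
    ).to_csv(out / "outcomes.csv", index=False)


def read_cohort(in_dir: str | Path) -> list[PatientRecord]:
    out = Path(in_dir)
    meas = pd.read_csv(out / "measurements.csv", dtype={"patient_id": str},
                       float_precision="round_trip")
    outc = pd.read_csv(out / "outcomes.csv", dtype={"patient_id": str})
    by_patient: dict[str, list] = {pid: [] for pid in outc["patient_id"]}
    for pid, item, t, v in meas.itertuples(index=False):
        by_patient[pid].append((item, float(t), float(v)))
    return [
        PatientRecord(patient_id=pid, outcome=int(o), measurements=by_patient.get(pid, []))
        for pid, o in outc.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Feature matrices


def write_feature_matrix(fm: FeatureMatrix, prefix: str | Path,
                         split_seed: int | None = None) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("patient_id\toutcome\t" + "\t".join(fm.item_labels) + "\n")
        for pid, y, row in zip(fm.patient_ids, fm.outcomes, fm.X):
            fh.write(pid + "\t" + str(int(y)) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    sidecar = {
        "item_labels": list(fm.item_labels),
        "scale_means": None if fm.scale_means is None else [_fmt(v) for v in fm.scale_means],
        "split_seed": split_seed,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    ids, ys, rows = [], [], []
    with open(prefix.with_suffix(".tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            ys.append(int(parts[1]))
            rows.append([float(v) for v in parts[2:]])
    means = sidecar["scale_means"]
    return FeatureMatrix(
        X=np.array(rows, dtype=float),
        outcomes=np.array(ys, dtype=int),
        item_labels=header[2:],
        patient_ids=ids,
        scale_means=None if means is None else np.array([float(v) for v in means]),
    )


# ---------------------------------------------------------------------------
# Parameter vectors


def write_params(w: np.ndarray, path: str | Path, kind: str, shape_info: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# kind {kind}\n")
        fh.write("# shape " + json.dumps(shape_info) + "\n")
        for v in np.asarray(w, dtype=float).ravel():
            fh.write(_fmt(v) + "\n")


def read_params(path: str | Path) -> tuple[np.ndarray, str, dict]:
    kind, shape_info, values = "", {}, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# kind"):
                kind = line.split(maxsplit=2)[2]
            elif line.startswith("# shape"):
                shape_info = json.loads(line.split(maxsplit=2)[2])
            elif line and not line.startswith("#"):
                values.append(float(line))
    return np.array(values), kind, shape_info


# ---------------------------------------------------------------------------
# Minima and transition-state databases


def write_minima(db: MinimaDatabase, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    offset = 0
    with open(out / "minima.index", "w") as idx, open(out / "minima.weights", "w") as wts:
        idx.write(f"# dedupe_tol {_fmt(db.dedupe_tol)}\n")
        idx.write("# E rms_grad n_iter offset\n")
        for m in db:
            idx.write(f"{_fmt(m.E)} {_fmt(m.rms_grad)} {m.n_iter} {offset}\n")
            for v in m.W:
                wts.write(_fmt(v) + "\n")
            offset += m.W.size


def read_minima(in_dir: str | Path) -> MinimaDatabase:
    out = Path(in_dir)
    with open(out / "minima.weights") as fh:
        weights = np.array([float(line) for line in fh if line.strip()])
    entries = []
    dedupe_tol = 1e-8
    with open(out / "minima.index") as fh:
        for line in fh:
            if line.startswith("# dedupe_tol"):
                dedupe_tol = float(line.split()[2])
                continue
            if line.startswith("#") or not line.strip():
                continue
            e, rms, n_it, off = line.split()
            entries.append((float(e), float(rms), int(n_it), int(off)))
    db = MinimaDatabase(dedupe_tol=dedupe_tol)
    for k, (e, rms, n_it, off) in enumerate(entries):
        end = entries[k + 1][3] if k + 1 < len(entries) else weights.size
        db.add(Minimum(W=weights[off:end].copy(), E=e, rms_grad=rms, n_iter=n_it))
    return db


def write_stationary_points(spdb: StationaryPointDatabase, out_dir: str | Path) -> None:
    out = Path(out_dir)
    write_minima(spdb.minima, out)
    offset = 0
    with open(out / "ts.index", "w") as idx, open(out / "ts.weights", "w") as wts:
        idx.write(f"# connected {int(spdb.connected)}\n")
        idx.write("# E neg_eigenvalue min1 min2 offset\n")
        for ts in spdb.transition_states:
            idx.write(
                f"{_fmt(ts.E)} {_fmt(ts.neg_eigenvalue)} "
                f"{ts.min_pair[0]} {ts.min_pair[1]} {offset}\n"
            )
            for v in ts.W:
                wts.write(_fmt(v) + "\n")
            for v in ts.neg_eigenvector:
                wts.write(_fmt(v) + "\n")
            offset += 2 * ts.W.size


def read_stationary_points(in_dir: str | Path) -> StationaryPointDatabase:
    out = Path(in_dir)
    minima = read_minima(out)
    spdb = StationaryPointDatabase(minima=minima)
    ts_weights_path = out / "ts.weights"
    entries = []
    with open(out / "ts.index") as fh:
        for line in fh:
            if line.startswith("# connected"):
                spdb.connected = bool(int(line.split()[2]))
                continue
            if line.startswith("#") or not line.strip():
                continue
            e, lam, i, j, off = line.split()
            entries.append((float(e), float(lam), int(i), int(j), int(off)))
    if entries:
        with open(ts_weights_path) as fh:
            weights = np.array([float(line) for line in fh if line.strip()])
        for k, (e, lam, i, j, off) in enumerate(entries):
            end = entries[k + 1][4] if k + 1 < len(entries) else weights.size
            block = weights[off:end]
            dim = block.size // 2
            spdb.transition_states.append(
                TransitionState(
                    W=block[:dim].copy(), E=e, neg_eigenvalue=lam,
                    neg_eigenvector=block[dim:].copy(), min_pair=(i, j),
                    degenerate=i == j,
                )
            )
    return spdb


# ---------------------------------------------------------------------------
# Disconnectivity exports


def dgraph_edges_tsv(dg, path: str | Path) -> None:
    """Edge list of the disconnectivity tree: child -> parent with levels."""
    lines = ["node\tparent\tlevel\tminima"]

    def walk(node, parent_id, counter=[0]):
        my_id = f"n{counter[0]}"
        counter[0] += 1
        lines.append(
            f"{my_id}\t{parent_id}\t{_fmt(node.level)}\t"
            + ",".join(str(i) for i in node.minima)
        )
        for c in node.children:
            walk(c, my_id)

    walk(dg.root, "-")
    Path(path).write_text("\n".join(lines) + "\n")


def dgraph_dot(dg, path: str | Path) -> None:
    """Graphviz DOT rendering of the disconnectivity tree."""
    lines = ["digraph disconnectivity {", "  node [shape=point];"]
    counter = [0]

    def walk(node):
        my_id = f"n{counter[0]}"
        counter[0] += 1
        if node.is_leaf:
            lines.append(
                f'  {my_id} [shape=circle,label="m{node.minima[0]}",'
                f'xlabel="{node.level:.4g}"];'
            )
        else:
            lines.append(f'  {my_id} [xlabel="{node.level:.4g}"];')
        for c in node.children:
            cid = walk(c)
            lines.append(f"  {my_id} -> {cid};")
        return my_id

    walk(dg.root)
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
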