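"""Reading and writing the pipeline's tabular formats.

All artifacts are plain text: TSV for matrices, trajectories and cluster
tables (via pandas), JSON for reports, model weights and ODE parameters.
The expression input format is a genes x samples TSV whose columns are
named ``<patient>_<timepoint>`` together with a samples sheet mapping each
column to (patient, time point label, hours, pre-resection flag).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpress import ClusterAssignment, ClusterTrajectory, CoexpressionNetwork
from .grid import TimeGrid
from .liverode import OdeParams, Trajectory, STATE_FIELDS
from .neuralmap import NetSpec, TrainedMap
from .tensor import ExpressionTensor
from .twin import EvalReport, TwinForecast


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(matrix_path, samples_path) -> tuple[ExpressionTensor, TimeGrid]:
    """Load a genes x samples matrix plus its samples sheet.

    The samples sheet is a TSV with columns ``sample`` (matching a matrix
    column), ``patient``, ``timepoint``, ``hours`` and ``pre_resection``
    (0/1).  Cells absent from the matrix (NaN) are masked.
    """
    mat = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    required = {"sample", "patient", "timepoint", "hours", "pre_resection"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"samples sheet must contain columns {sorted(required)}")
    missing_cols = set(sheet["sample"]) - set(mat.columns)
    if missing_cols:
        raise ValueError(f"samples sheet references absent columns {sorted(missing_cols)}")

    tp = sheet.drop_duplicates("timepoint").sort_values(
        by=["pre_resection", "hours"], ascending=[False, True]
    )
    grid = TimeGrid(
        labels=tuple(tp["timepoint"]),
        hours=tuple(float(h) for h in tp["hours"]),
        pre_resection=tuple(bool(p) for p in tp["pre_resection"]),
    )
    patients = tuple(pd.unique(sheet["patient"]))
    genes = tuple(mat.index)
    values = np.zeros((len(genes), len(patients), len(grid)))
    mask = np.zeros_like(values, dtype=bool)
    t_index = {lab: i for i, lab in enumerate(grid.labels)}
    p_index = {p: i for i, p in enumerate(patients)}
    for _, row in sheet.iterrows():
        col = mat[row["sample"]].to_numpy(dtype=float)
        pi, ti = p_index[row["patient"]], t_index[row["timepoint"]]
        ok = np.isfinite(col)
        values[ok, pi, ti] = col[ok]
        mask[:, pi, ti] = ok
    return ExpressionTensor(values, mask, "raw", genes, patients), grid


def write_expression(
    tensor: ExpressionTensor, grid: TimeGrid, matrix_path, samples_path
) -> None:
    """Write a tensor back to the matrix + samples-sheet format."""
    cols, rows_sheet = [], []
    data = {}
    for pi, pid in enumerate(tensor.patient_ids):
        for ti, label in enumerate(grid.labels):
            if not tensor.mask[:, pi, ti].any():
                continue
            name = f"{pid}_{label.replace(' ', '')}"
            col = np.where(tensor.mask[:, pi, ti], tensor.values[:, pi, ti], np.nan)
            data[name] = col
            cols.append(name)
            rows_sheet.append({
                "sample": name, "patient": pid, "timepoint": label,
                "hours": grid.hours[ti],
                "pre_resection": int(grid.pre_resection[ti]),
            })
    pd.DataFrame(data, index=list(tensor.gene_ids)).to_csv(matrix_path, sep="\t")
    pd.DataFrame(rows_sheet).to_csv(samples_path, sep="\t", index=False)


def write_tensor(tensor: ExpressionTensor, grid: TimeGrid, path) -> None:
    """Long-format TSV (gene, patient, time, value, observed)."""
    tensor.to_frame(grid.labels).to_csv(path, sep="\t", index=False)


def read_tensor(path, scale: str, grid: TimeGrid) -> ExpressionTensor:
    frame = pd.read_csv(path, sep="\t")
    return ExpressionTensor.from_frame(frame, scale, grid.labels)


# ---------------------------------------------------------------------------
# clustering artifacts
# ---------------------------------------------------------------------------

def write_assignment(assign: ClusterAssignment, path) -> None:
    pd.DataFrame({
        "gene": assign.genes,
        "cluster": assign.labels,
        "module": [assign.module_map.get(int(c), "") for c in assign.labels],
    }).to_csv(path, sep="\t", index=False)


def write_cluster_trajectory(traj: ClusterTrajectory, grid: TimeGrid, path) -> None:
    rows = []
    for ci, c in enumerate(traj.cluster_ids):
        for pi, pid in enumerate(traj.patient_ids):
            for ti, label in enumerate(grid.labels):
                if not traj.mask[ci, pi, ti]:
                    continue
                rows.append({
                    "cluster": c, "patient": pid, "time": label,
                    "hours": grid.hours[ti],
                    "mean_log2fc": traj.values[ci, pi, ti],
                    "sd": traj.spread[ci, pi, ti],
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network_summary(net: CoexpressionNetwork, K: int, path) -> None:
    Path(path).write_text(json.dumps({
        "n_genes": net.n_genes,
        "beta": net.beta,
        "scale_free_r2": net.sft_r2,
        "K": K,
    }, indent=2))


# ---------------------------------------------------------------------------
# ODE parameters and trajectories
# ---------------------------------------------------------------------------

def write_params(params: OdeParams, path) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=2))


def read_params(path) -> OdeParams:
    return OdeParams(**json.loads(Path(path).read_text()))


def write_trajectory(traj: Trajectory, path) -> None:
    frame = pd.DataFrame(traj.states, columns=list(STATE_FIELDS))
    frame.insert(0, "time_h", traj.times)
    frame["volume"] = traj.volume
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trained maps
# ---------------------------------------------------------------------------

def write_map(trained: TrainedMap, path) -> None:
    """Serialize a trained map to a single JSON file (weights inline)."""
    spec = trained.spec
    payload = {
        "direction": trained.direction,
        "spec": {
            "input_dim": spec.input_dim, "output_dim": spec.output_dim,
            "hidden_dims": list(spec.hidden_dims), "dropout_p": spec.dropout_p,
            "seed": spec.seed, "learning_rate": spec.learning_rate,
            "epochs": spec.epochs, "batch_size": spec.batch_size,
            "standardize": spec.standardize,
        },
        "weights": [w.tolist() for w in trained.weights],
        "biases": [b.tolist() for b in trained.biases],
        "x_mean": trained.x_mean.tolist(), "x_std": trained.x_std.tolist(),
        "y_mean": trained.y_mean.tolist(), "y_std": trained.y_std.tolist(),
        "training_log": trained.training_log.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_map(path) -> TrainedMap:
    payload = json.loads(Path(path).read_text())
    s = payload["spec"]
    spec = NetSpec(
        input_dim=s["input_dim"], output_dim=s["output_dim"],
        hidden_dims=tuple(s["hidden_dims"]), dropout_p=s["dropout_p"],
        seed=s["seed"], learning_rate=s["learning_rate"], epochs=s["epochs"],
        batch_size=s["batch_size"], standardize=s["standardize"],
    )
    return TrainedMap(
        spec=spec,
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        x_mean=np.array(payload["x_mean"]), x_std=np.array(payload["x_std"]),
        y_mean=np.array(payload["y_mean"]), y_std=np.array(payload["y_std"]),
        training_log=np.array(payload["training_log"]),
        direction=payload["direction"],
    )


# ---------------------------------------------------------------------------
# forecasts and evaluation reports
# ---------------------------------------------------------------------------

def write_forecast(fc: TwinForecast, path) -> None:
    rows = []
    for j, gi in enumerate(fc.future_indices):
        for ci in range(fc.predicted.shape[0]):
            rows.append({
                "patient": fc.patient, "t0": fc.t0_label,
                "time": fc.grid.labels[gi], "hours": fc.grid.hours[gi],
                "cluster": ci + 1,
                "predicted_log2fc": fc.predicted[ci, j],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(report: EvalReport, path) -> None:
    def _clean(x):
        return [None if not np.isfinite(v) else float(v) for v in np.asarray(x).ravel()]

    Path(path).write_text(json.dumps({
        "cluster_ids": list(report.cluster_ids),
        "mse": _clean(report.mse),
        "pearson": _clean(report.pearson),
        "pearson_defined": [bool(b) for b in report.pearson_defined],
        "mean_mse": report.mean_mse if np.isfinite(report.mean_mse) else None,
        "mean_pearson": (report.mean_pearson
                         if np.isfinite(report.mean_pearson) else None),
        "per_time_mse": _clean(report.per_time_mse),
        "time_indices": [int(i) for i in report.time_indices],
        "n_masked_skipped": report.n_masked_skipped,
    }, indent=2))
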