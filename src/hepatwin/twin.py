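"""The digital twin loop: map, simulate, reverse-map, evaluate.

Given a patient's cluster expression at an initial time point and their
resection fraction, the twin forward-maps expression to a mechanistic
state, simulates the regeneration model to the remaining grid points, and
reverse-maps each simulated state to predicted cluster expression.
Predictions are scored against the observed cluster trajectories with
per-cluster mean squared error and Pearson correlation, and the whole
exercise can be repeated from several initial time points to probe
robustness of the forecast to the starting point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coexpress import ClusterTrajectory
from .grid import TimeGrid
from .liverode import OdeParams, apply_resection, simulate, state_from_vector
from .neuralmap import TrainedMap, apply_map
from .tensor import ExpressionTensor


@dataclass
class TwinForecast:
    """Predicted cluster expression at every grid point after t0."""

    patient: str
    t0_label: str
    fraction: float
    grid: TimeGrid
    predicted: np.ndarray          # (K, n_future) cluster log2fc
    future_indices: np.ndarray     # grid indices the predictions cover
    simulated_states: np.ndarray   # (n_future, S)
    initial_expression: np.ndarray  # the observed K-vector used at t0


@dataclass
class EvalReport:
    """Cluster-wise and averaged forecast accuracy."""

    cluster_ids: tuple[int, ...]
    mse: np.ndarray                 # per cluster; NaN if no scored points
    pearson: np.ndarray             # per cluster; NaN where undefined
    pearson_defined: np.ndarray     # bool per cluster
    mean_mse: float
    mean_pearson: float
    per_time_mse: np.ndarray        # (n_future,) across clusters; NaN-skipped
    time_indices: np.ndarray
    n_masked_skipped: int = 0


def run_twin(
    expr0: np.ndarray,
    f: float,
    t0_label: str,
    grid: TimeGrid,
    fwd: TrainedMap,
    params: OdeParams,
    rev: TrainedMap,
    *,
    patient: str = "?",
    include_fraction: bool = True,
) -> TwinForecast:
    """One pass of the twin loop for a single patient.

    ``expr0`` is the observed K-cluster vector at ``t0_label``.  Starting
    from the baseline means the forward-mapped state is pre-resection and
    the resection is applied at hour 0; for post-operative starts the
    mapped state is already post-resection and is integrated from t0's
    clock time.
    """
    expr0 = np.asarray(expr0, dtype=float)
    xin = np.concatenate([expr0, [f]]) if include_fraction else expr0
    if xin.shape[0] != fwd.spec.input_dim:
        raise ValueError(
            "forward-map input width mismatch: is the fraction feature "
            "configured consistently?"
        )
    state_vec = apply_map(fwd, xin)
    if not np.all(np.isfinite(state_vec)):
        raise ValueError("forward map produced non-finite state")
    state_vec = np.clip(state_vec, 0.0, None)
    state0 = state_from_vector(state_vec)

    t0_idx = grid.index_of(t0_label)
    hours = grid.hours_array
    pre = np.asarray(grid.pre_resection)
    future = np.flatnonzero((np.arange(len(grid)) > t0_idx) & ~pre)
    if future.size == 0:
        return TwinForecast(
            patient, t0_label, f, grid,
            np.empty((rev.spec.output_dim, 0)), future,
            np.empty((0, fwd.spec.output_dim)), expr0,
        )

    if pre[t0_idx]:
        # baseline start: resect the mapped (pre-operative) state at hour 0
        state0 = apply_resection(state0, f)
        t_start = 0.0
    else:
        t_start = float(hours[t0_idx])
    traj = simulate(params, state0, hours[future], t_start=t_start)
    predicted = apply_map(rev, traj.states).T  # (K, n_future)
    return TwinForecast(
        patient, t0_label, f, grid, predicted, future, traj.states, expr0
    )


def evaluate(
    forecast: TwinForecast,
    observed: ClusterTrajectory,
    *,
    min_points: int = 2,
) -> EvalReport:
    """Score a forecast against the observed cluster trajectories.

    Only observed (unmasked) post-t0 points count.  Clusters with fewer
    than ``min_points`` scored points or zero variance get an undefined
    Pearson flag and are excluded from the correlation average.
    """
    pi = observed.patient_ids.index(forecast.patient)
    K = observed.K
    if forecast.predicted.shape[0] != K:
        raise ValueError("forecast and observation cluster counts differ")
    idx = forecast.future_indices
    obs = observed.values[:, pi, :][:, idx]     # (K, n_future)
    msk = observed.mask[:, pi, :][:, idx]
    pred = forecast.predicted

    mse = np.full(K, np.nan)
    pear = np.full(K, np.nan)
    defined = np.zeros(K, dtype=bool)
    skipped = int((~msk).sum())
    for c in range(K):
        m = msk[c]
        if not m.any():
            continue
        d = pred[c, m] - obs[c, m]
        mse[c] = float(np.mean(d ** 2))
        if m.sum() >= min_points and np.std(obs[c, m]) > 0 and np.std(pred[c, m]) > 0:
            pear[c] = float(stats.pearsonr(pred[c, m], obs[c, m]).statistic)
            defined[c] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_time = np.where(
            msk.any(axis=0),
            np.nanmean(np.where(msk, (pred - obs) ** 2, np.nan), axis=0),
            np.nan,
        )
    mean_mse = float(np.nanmean(mse)) if np.any(np.isfinite(mse)) else float("nan")
    mean_p = float(np.mean(pear[defined])) if defined.any() else float("nan")
    return EvalReport(
        cluster_ids=observed.cluster_ids,
        mse=mse, pearson=pear, pearson_defined=defined,
        mean_mse=mean_mse, mean_pearson=mean_p,
        per_time_mse=per_time, time_indices=idx,
        n_masked_skipped=skipped,
    )


def robustness_compare(
    patient: str,
    observed: ClusterTrajectory,
    f: float,
    grid: TimeGrid,
    fwd: TrainedMap,
    params: OdeParams,
    rev: TrainedMap,
    t0_choices: tuple[str, ...] = ("Before Surgery", "5 min", "30 min"),
    *,
    include_fraction: bool = True,
) -> dict[str, tuple[TwinForecast, EvalReport]]:
    """Run the twin from several initial time points and tabulate accuracy.

    A requested t0 with no observed expression for the patient is skipped
    with a warning.
    """
    pi = observed.patient_ids.index(patient)
    out: dict[str, tuple[TwinForecast, EvalReport]] = {}
    for label in t0_choices:
        ti = grid.index_of(label)
        if not observed.mask[:, pi, ti].all():
            warnings.warn(
                f"{patient}: expression at {label!r} not fully observed; skipped",
                stacklevel=2,
            )
            continue
        expr0 = observed.values[:, pi, ti]
        fc = run_twin(
            expr0, f, label, grid, fwd, params, rev,
            patient=patient, include_fraction=include_fraction,
        )
        out[label] = (fc, evaluate(fc, observed))
    return out


def split_cohort(
    t: ExpressionTensor,
    *,
    train_fraction: float = 2 / 3,
    train_patients: tuple[str, ...] | None = None,
    test_patients: tuple[str, ...] | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Availability-based train/test split of the cohort.

    Patients are ordered by descending count of observed time points (ties
    broken by patient id); the top ``train_fraction`` go to training.
    Explicit patient lists override the rule.
    """
    if train_patients is not None or test_patients is not None:
        ids = set(t.patient_ids)
        train = tuple(train_patients or ())
        test = tuple(test_patients or tuple(p for p in t.patient_ids if p not in set(train)))
        if train_patients is None:
            train = tuple(p for p in t.patient_ids if p not in set(test))
        unknown = (set(train) | set(test)) - ids
        if unknown:
            raise ValueError(f"unknown patients {sorted(unknown)}")
        return train, test
    # a time point counts as available if any gene is observed there
    avail = t.mask.any(axis=0).sum(axis=1)  # per patient
    order = sorted(
        range(t.n_patients), key=lambda i: (-int(avail[i]), t.patient_ids[i])
    )
    n_train = int(round(train_fraction * t.n_patients))
    train = tuple(t.patient_ids[i] for i in order[:n_train])
    test = tuple(t.patient_ids[i] for i in order[n_train:])
    return train, test
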