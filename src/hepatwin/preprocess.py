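"""Preprocessing of longitudinal expression data.

The pipeline turns a raw expression tensor into baseline-relative log2 fold
changes in a fixed, scale-tag-enforced order:

1. :func:`impute_missing` — fill missing cells with the cross-patient mean
   at the same gene and time point;
2. :func:`correct_negatives` — replace biologically unrealistic negative
   values with the cross-patient mean of non-negative observations;
3. :func:`log_transform` — ``x -> log2(1 + x)``;
4. :func:`to_log2fc` — subtract each patient's preoperative baseline.

:func:`select_degs` then selects regeneration-specific genes: at least a
two-fold change (|log2fc| >= 1) sustained over two consecutive
post-operative time points, excluding genes that already move 1.5-fold or
more at pre-resection samples (nonspecific effects of the abdominal
incision).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .grid import TimeGrid
from .tensor import ExpressionTensor


class ImputeResult(NamedTuple):
    tensor: ExpressionTensor
    imputed: np.ndarray  # boolean (gene, patient, time), True where filled
    unfilled: list[tuple[int, int]]  # (gene, time) observed in zero patients


class CorrectResult(NamedTuple):
    tensor: ExpressionTensor
    replaced: np.ndarray  # boolean, True where a negative was replaced
    zero_filled: list[tuple[int, int, int]]  # cells with no usable neighbors


class Log2fcResult(NamedTuple):
    tensor: ExpressionTensor
    missing_baseline: list[tuple[int, int]]  # (gene, patient) masked out


@dataclass
class DegReport:
    """Outcome of fold-change based differential-expression filtering."""

    n_input: int
    n_twofold: int
    n_presurgical_excluded: int
    n_selected: int
    selected: tuple[str, ...]
    max_consecutive_log2fc: np.ndarray = field(repr=False)
    pre_resection_log2fc: np.ndarray = field(repr=False)
    twofold_flags: np.ndarray = field(repr=False)
    presurgical_flags: np.ndarray = field(repr=False)


def impute_missing(t: ExpressionTensor) -> ImputeResult:
    """Fill missing cells with the mean over other patients at (gene, time).

    Cells observed in zero patients stay masked and are reported rather than
    silently filled.  Idempotent: a second pass finds nothing to fill.
    """
    if t.scale != "raw":
        raise ValueError("imputation operates on raw-scale tensors")
    out = t.copy()
    vals, mask = out.values, out.mask
    n_obs = mask.sum(axis=1)  # (gene, time)
    sums = np.where(mask, vals, 0.0).sum(axis=1)
    imputed = np.zeros_like(mask)
    unfilled: list[tuple[int, int]] = []
    fillable = n_obs > 0
    for p in range(t.n_patients):
        need = ~mask[:, p, :] & fillable
        if need.any():
            gi, ti = np.nonzero(need)
            vals[gi, p, ti] = sums[gi, ti] / n_obs[gi, ti]
            mask[gi, p, ti] = True
            imputed[gi, p, ti] = True
    dead = ~fillable & (~t.mask).any(axis=1)
    for gi, ti in zip(*np.nonzero(dead)):
        unfilled.append((int(gi), int(ti)))
    if unfilled:
        warnings.warn(
            f"{len(unfilled)} (gene, time) cells observed in no patient remain masked",
            stacklevel=2,
        )
    return ImputeResult(out, imputed, unfilled)


def correct_negatives(t: ExpressionTensor) -> CorrectResult:
    """Replace negative values with the cross-patient non-negative mean.

    A negative cell with no non-negative observed counterpart in any other
    patient is set to 0 and reported.  Idempotent.
    """
    if t.scale != "raw":
        raise ValueError("negative correction operates on raw-scale tensors")
    out = t.copy()
    vals, mask = out.values, out.mask
    ok = mask & (vals >= 0)
    n_ok = ok.sum(axis=1)
    sum_ok = np.where(ok, vals, 0.0).sum(axis=1)
    replaced = np.zeros_like(mask)
    zero_filled: list[tuple[int, int, int]] = []
    neg = mask & (vals < 0)
    for gi, pi, ti in zip(*np.nonzero(neg)):
        # means over *other* patients: this cell is negative, so excluded
        # from ok already
        if n_ok[gi, ti] > 0:
            vals[gi, pi, ti] = sum_ok[gi, ti] / n_ok[gi, ti]
        else:
            vals[gi, pi, ti] = 0.0
            zero_filled.append((int(gi), int(pi), int(ti)))
        replaced[gi, pi, ti] = True
    if zero_filled:
        warnings.warn(
            f"{len(zero_filled)} negative cells had no non-negative counterpart; set to 0",
            stacklevel=2,
        )
    return CorrectResult(out, replaced, zero_filled)


def log_transform(t: ExpressionTensor) -> ExpressionTensor:
    """Apply ``x -> log2(1 + x)`` to every observed cell; scale becomes log1p."""
    if t.scale == "log1p":
        return t.copy()  # idempotent entry point
    if t.scale != "raw":
        raise ValueError("log transform operates on raw-scale tensors")
    obs = t.values[t.mask]
    if obs.size and np.min(obs) < 0:
        raise ValueError("negative values present; run correct_negatives first")
    out = t.copy()
    out.values[out.mask] = np.log2(1.0 + out.values[out.mask])
    return out.with_scale("log1p")


def to_log2fc(t: ExpressionTensor, grid: TimeGrid) -> Log2fcResult:
    """Subtract each patient's baseline; the baseline column becomes 0.

    Gene/patient pairs whose baseline is missing (even after imputation) are
    flagged and fully masked — the baseline is never reconstructed from
    post-operative values.
    """
    if t.scale != "log1p":
        raise ValueError("log2fc conversion requires a log1p tensor")
    if len(grid) != t.n_times:
        raise ValueError("grid length does not match tensor time axis")
    b = grid.baseline_index
    out = t.copy()
    base = out.values[:, :, b]
    base_ok = out.mask[:, :, b]
    missing: list[tuple[int, int]] = []
    out.values -= base[:, :, None]
    out.values[:, :, b] = 0.0
    bad_g, bad_p = np.nonzero(~base_ok)
    for gi, pi in zip(bad_g, bad_p):
        missing.append((int(gi), int(pi)))
    out.mask[bad_g, bad_p, :] = False
    out.values[~out.mask] = 0.0
    if missing:
        warnings.warn(
            f"{len(missing)} gene/patient pairs lack a baseline and were masked",
            stacklevel=2,
        )
    return Log2fcResult(out.with_scale("log2fc"), missing)


def _mean_profiles(t: ExpressionTensor) -> np.ndarray:
    """Cross-patient mean log2fc per gene and time; NaN where unobserved."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = t.masked().mean(axis=1)
    return np.ma.filled(m, np.nan)


def select_degs(
    t: ExpressionTensor,
    grid: TimeGrid,
    *,
    twofold_log2: float = 1.0,
    prefold: float = 1.5,
    min_consecutive: int = 2,
    per_patient: bool = False,
) -> DegReport:
    """Select genes with a sustained >=2-fold regeneration-specific response.

    A gene passes the fold-change rule iff |log2fc| >= ``twofold_log2`` at
    each of ``min_consecutive`` consecutive post-operative time points of
    its cross-patient mean profile (or of any single patient's profile when
    ``per_patient``).  It is excluded as nonspecific iff |log2fc| >=
    log2(``prefold``) at any pre-resection sample other than the baseline.
    """
    if t.scale != "log2fc":
        raise ValueError("DEG selection requires a log2fc tensor")
    post = grid.postop_indices
    if len(post) < min_consecutive:
        raise ValueError("grid has too few post-operative points")

    if per_patient:
        profiles = np.where(t.mask, t.values, np.nan)  # (g, p, T)
    else:
        profiles = _mean_profiles(t)[:, None, :]  # (g, 1, T)

    post_prof = profiles[:, :, post]
    hits = (np.abs(post_prof) >= twofold_log2) & ~np.isnan(post_prof)
    n_post = hits.shape[2]
    ok = hits[:, :, : n_post - min_consecutive + 1]
    for k in range(1, min_consecutive):
        ok = ok & hits[:, :, k: n_post - min_consecutive + 1 + k]
    twofold = ok.any(axis=(1, 2))

    mean_prof = _mean_profiles(t)
    pre_idx = grid.pre_resection_indices
    pre_thresh = np.log2(prefold)
    if len(pre_idx):
        pre_vals = mean_prof[:, pre_idx]
        presurg = np.nanmax(
            np.abs(np.where(np.isnan(pre_vals), 0.0, pre_vals)), axis=1
        ) >= pre_thresh
        pre_flag_vals = np.where(np.isnan(pre_vals), 0.0, pre_vals)
        pre_report = np.max(np.abs(pre_flag_vals), axis=1)
    else:
        presurg = np.zeros(t.n_genes, dtype=bool)
        pre_report = np.zeros(t.n_genes)

    selected_mask = twofold & ~presurg
    selected = tuple(g for g, s in zip(t.gene_ids, selected_mask) if s)

    # per-gene max fold change over any consecutive post-op window
    abs_post = np.abs(np.where(np.isnan(mean_prof[:, post]), 0.0, mean_prof[:, post]))
    if abs_post.shape[1] >= min_consecutive:
        windows = np.stack(
            [abs_post[:, k: abs_post.shape[1] - min_consecutive + k + 1]
             for k in range(min_consecutive)], axis=0,
        )
        max_consec = windows.min(axis=0).max(axis=1)
    else:
        max_consec = np.zeros(t.n_genes)

    return DegReport(
        n_input=t.n_genes,
        n_twofold=int(twofold.sum()),
        n_presurgical_excluded=int((twofold & presurg).sum()),
        n_selected=int(selected_mask.sum()),
        selected=selected,
        max_consecutive_log2fc=max_consec,
        pre_resection_log2fc=pre_report,
        twofold_flags=twofold,
        presurgical_flags=presurg,
    )


def preprocess_pipeline(
    t: ExpressionTensor, grid: TimeGrid
) -> tuple[ExpressionTensor, dict]:
    """Run impute -> correct -> log -> log2fc and collect the reports."""
    imp = impute_missing(t)
    cor = correct_negatives(imp.tensor)
    logt = log_transform(cor.tensor)
    fc = to_log2fc(logt, grid)
    reports = {
        "n_imputed": int(imp.imputed.sum()),
        "unfilled": imp.unfilled,
        "n_negative_replaced": int(cor.replaced.sum()),
        "zero_filled": cor.zero_filled,
        "missing_baseline": fc.missing_baseline,
    }
    return fc.tensor, reports
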