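"""End-to-end study pipeline: from a log2fc tensor to held-out forecasts.

This ties the stages together the way the study design prescribes:

1. split the cohort by availability (the lowest-availability third, whose
   late samples are missing, is the natural test set);
2. select regeneration-specific genes and discover K temporal clusters on
   the training patients;
3. simulate each training patient's mechanistic trajectory from their known
   resection fraction and train the forward (expression -> state) and
   reverse (state -> expression) maps on the paired samples;
4. run the twin for each held-out patient from an initial time point and
   score the forecast against their observed cluster trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coexpress import ClusterAssignment, ClusterTrajectory, cluster_pipeline, cluster_profiles
from .grid import TimeGrid
from .liverode import OdeParams, simulate_resection, STATE_DIM
from .neuralmap import NetSpec, TrainedMap, build_training_pairs, train_map
from .preprocess import select_degs
from .tensor import ExpressionTensor
from .twin import EvalReport, TwinForecast, evaluate, run_twin, split_cohort


@dataclass
class FittedTwin:
    """A trained digital twin and the artifacts behind it."""

    assignment: ClusterAssignment
    observed: ClusterTrajectory          # whole-cohort cluster trajectories
    fwd: TrainedMap
    rev: TrainedMap
    params: OdeParams
    grid: TimeGrid
    fractions: dict[str, float]
    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    include_fraction: bool = True

    def forecast(self, patient: str, t0_label: str) -> TwinForecast:
        pi = self.observed.patient_ids.index(patient)
        ti = self.grid.index_of(t0_label)
        if not self.observed.mask[:, pi, ti].all():
            raise ValueError(f"{patient} has no observed expression at {t0_label!r}")
        expr0 = self.observed.values[:, pi, ti]
        return run_twin(
            expr0, self.fractions[patient], t0_label, self.grid,
            self.fwd, self.params, self.rev,
            patient=patient, include_fraction=self.include_fraction,
        )

    def evaluate_patient(self, patient: str, t0_label: str) -> EvalReport:
        return evaluate(self.forecast(patient, t0_label), self.observed)


def fit_twin(
    tensor: ExpressionTensor,
    grid: TimeGrid,
    fractions: dict[str, float],
    *,
    K: int = 15,
    seed: int = 0,
    params: OdeParams | None = None,
    select_genes: bool = True,
    min_module_size: int = 30,
    include_fraction: bool = True,
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    train_patients: tuple[str, ...] | None = None,
    test_patients: tuple[str, ...] | None = None,
) -> FittedTwin:
    """Fit the full twin on a log2fc tensor with known resection fractions."""
    if tensor.scale != "log2fc":
        raise ValueError("fit_twin expects a log2fc tensor")
    params = params or OdeParams()
    train, test = split_cohort(
        tensor, train_patients=train_patients, test_patients=test_patients
    )

    if select_genes:
        report = select_degs(tensor, grid)
        keep = [tensor.gene_index(g) for g in report.selected]
        if not keep:
            raise ValueError("no genes passed the fold-change filters")
        tensor = ExpressionTensor(
            tensor.values[keep], tensor.mask[keep], "log2fc",
            report.selected, tensor.patient_ids,
        )

    # cluster on the training patients only; apply the labels cohort-wide
    tr_idx = [tensor.patient_ids.index(p) for p in train]
    train_tensor = ExpressionTensor(
        tensor.values[:, tr_idx], tensor.mask[:, tr_idx], "log2fc",
        tensor.gene_ids, train,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assignment, _, net = cluster_pipeline(
            train_tensor, grid, K=K, seed=seed, min_size=min_module_size
        )
    if net.genes != tensor.gene_ids:  # genes dropped for zero variance
        keep = [tensor.gene_index(g) for g in net.genes]
        tensor = ExpressionTensor(
            tensor.values[keep], tensor.mask[keep], "log2fc",
            net.genes, tensor.patient_ids,
        )
    observed = cluster_profiles(tensor, assignment)

    sims = {p: simulate_resection(params, fractions[p], grid).states for p in train}
    train_traj = ClusterTrajectory(
        observed.values[:, tr_idx], observed.spread[:, tr_idx],
        observed.mask[:, tr_idx], observed.cluster_ids, train,
    )
    K_eff = observed.K
    fwd_spec = NetSpec(
        input_dim=K_eff + (1 if include_fraction else 0), output_dim=STATE_DIM,
        seed=seed, epochs=epochs, learning_rate=learning_rate,
    )
    rev_spec = NetSpec(
        input_dim=STATE_DIM, output_dim=K_eff,
        seed=seed + 1, epochs=epochs, learning_rate=learning_rate,
    )
    fwd_set = build_training_pairs(
        train_traj, sims, "forward",
        fractions=fractions, include_fraction=include_fraction,
    )
    rev_set = build_training_pairs(train_traj, sims, "reverse")
    fwd = train_map(fwd_set, fwd_spec, "forward")
    rev = train_map(rev_set, rev_spec, "reverse")

    return FittedTwin(
        assignment=assignment, observed=observed, fwd=fwd, rev=rev,
        params=params, grid=grid, fractions=dict(fractions),
        train_patients=train, test_patients=test,
        include_fraction=include_fraction,
    )


def heldout_scores(fitted: FittedTwin, t0_label: str = "Before Surgery"):
    """Per-test-patient evaluation reports from one initial time point."""
    return {p: fitted.evaluate_patient(p, t0_label) for p in fitted.test_patients}


def project_clusters(
    tensor: ExpressionTensor, assignment: ClusterAssignment
) -> ClusterTrajectory:
    """Cluster trajectories of any tensor under an existing assignment.

    Restricts the tensor to the assignment's genes (e.g. after gene
    selection inside :func:`fit_twin`) and averages members per cluster.
    """
    if tensor.gene_ids != assignment.genes:
        keep = [tensor.gene_index(g) for g in assignment.genes]
        tensor = ExpressionTensor(
            tensor.values[keep], tensor.mask[keep], tensor.scale,
            assignment.genes, tensor.patient_ids,
        )
    return cluster_profiles(tensor, assignment)
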