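"""Masked gene x patient x time expression tensors.

The :class:`ExpressionTensor` is the pipeline's central container: a dense
3-d array of expression values with a boolean observation mask and a scale
tag that enforces the legal preprocessing order
``raw -> log1p -> log2fc``.  Masked cells are ignored by every downstream
operation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SCALES = ("raw", "log1p", "log2fc")
_NEXT_SCALE = {"raw": ("raw", "log1p"), "log1p": ("log1p", "log2fc"), "log2fc": ("log2fc",)}


@dataclass
class ExpressionTensor:
    """Expression values on a (gene, patient, time) lattice with a mask.

    ``values[g, p, t]`` is meaningful only where ``mask[g, p, t]`` is True.
    ``scale`` is one of ``raw`` (linear expression units), ``log1p``
    (log2(1 + x)) or ``log2fc`` (log2 fold change vs the preoperative
    baseline).
    """

    values: np.ndarray
    mask: np.ndarray
    scale: str
    gene_ids: tuple[str, ...]
    patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 3:
            raise ValueError("expected a (gene, patient, time) array")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        g, p, _ = self.values.shape
        if len(self.gene_ids) != g or len(self.patient_ids) != p:
            raise ValueError("identifier lists do not match array shape")
        self.gene_ids = tuple(self.gene_ids)
        self.patient_ids = tuple(self.patient_ids)
        if self.scale != "raw":
            obs = self.values[self.mask]
            if self.scale == "log1p" and obs.size and np.min(obs) < 0:
                raise ValueError("log1p tensor contains negative values")

    # -- shape accessors --------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def with_scale(self, new_scale: str) -> "ExpressionTensor":
        """Return a shallow copy tagged with ``new_scale`` (legal moves only)."""
        if new_scale not in _NEXT_SCALE[self.scale]:
            raise ValueError(f"illegal scale transition {self.scale} -> {new_scale}")
        return replace(self, scale=new_scale)

    def copy(self) -> "ExpressionTensor":
        return ExpressionTensor(
            self.values.copy(), self.mask.copy(), self.scale,
            self.gene_ids, self.patient_ids,
        )

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=~self.mask)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    # -- tabular round trip -----------------------------------------------
    def to_frame(self, time_labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Long-format frame (gene, patient, time, value, observed)."""
        labels = time_labels or tuple(str(t) for t in range(self.n_times))
        g, p, t = np.meshgrid(
            np.arange(self.n_genes), np.arange(self.n_patients),
            np.arange(self.n_times), indexing="ij",
        )
        return pd.DataFrame({
            "gene": np.asarray(self.gene_ids)[g.ravel()],
            "patient": np.asarray(self.patient_ids)[p.ravel()],
            "time": np.asarray(labels)[t.ravel()],
            "value": self.values.ravel(),
            "observed": self.mask.ravel(),
        })

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        scale: str,
        time_labels: tuple[str, ...],
    ) -> "ExpressionTensor":
        genes = tuple(pd.unique(frame["gene"]))
        patients = tuple(pd.unique(frame["patient"]))
        gi = {g: i for i, g in enumerate(genes)}
        pi = {p: i for i, p in enumerate(patients)}
        ti = {t: i for i, t in enumerate(time_labels)}
        values = np.zeros((len(genes), len(patients), len(time_labels)))
        mask = np.zeros_like(values, dtype=bool)
        rows_g = frame["gene"].map(gi).to_numpy()
        rows_p = frame["patient"].map(pi).to_numpy()
        rows_t = frame["time"].astype(str).map(ti).to_numpy()
        values[rows_g, rows_p, rows_t] = frame["value"].to_numpy()
        mask[rows_g, rows_p, rows_t] = frame["observed"].to_numpy(dtype=bool)
        return cls(values, mask, scale, genes, patients)
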