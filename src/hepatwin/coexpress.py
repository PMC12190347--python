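"""Temporal gene-module discovery: weighted co-expression network + SOM.

The workflow mirrors weighted gene co-expression network analysis: a
pairwise-complete Pearson correlation over all observed (patient, time)
samples, an unsigned soft-thresholded adjacency ``|cor|^beta`` with beta
chosen by the scale-free-topology fit, the topological overlap matrix (TOM),
and average-linkage hierarchical clustering on ``1 - TOM``.  The resulting
groups are then refined by a seeded self-organizing map trained on the
cross-patient mean trajectories, whose best-matching units give the final
cluster assignment.  Clusters are summarized as per-patient mean/sd
trajectories and tagged as early-response, proliferation or long-term
recovery modules by the timing of their peak response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .grid import TimeGrid
from .tensor import ExpressionTensor

MODULE_TAGS = ("early", "proliferation", "long_term")


@dataclass
class CoexpressionNetwork:
    """Gene-gene correlation, soft-thresholded adjacency and TOM."""

    genes: tuple[str, ...]
    cor: np.ndarray
    beta: int | None = None
    adjacency: np.ndarray | None = None
    tom: np.ndarray | None = None
    sft_r2: float | None = None  # scale-free-topology fit at the chosen beta

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class ClusterAssignment:
    """Final gene -> cluster labels (1..K) with optional module tags."""

    genes: tuple[str, ...]
    labels: np.ndarray  # int cluster id in 1..K per gene
    K: int
    module_map: dict[int, str] = field(default_factory=dict)
    ambiguous: tuple[int, ...] = ()

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class ClusterTrajectory:
    """Per-cluster, per-patient mean log2fc trajectories with spread."""

    values: np.ndarray   # (K, patients, T) member-gene means
    spread: np.ndarray   # matching standard deviations
    mask: np.ndarray     # True where >= 1 member gene observed
    cluster_ids: tuple[int, ...]
    patient_ids: tuple[str, ...]

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def patient_matrix(self, patient: str) -> np.ndarray:
        """(K, T) mean trajectory of one patient."""
        return self.values[:, self.patient_ids.index(patient), :]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def correlation_matrix(t: ExpressionTensor, min_samples: int = 3) -> CoexpressionNetwork:
    """Pairwise-complete Pearson correlation over flattened observations.

    Genes with zero variance (or fewer than ``min_samples`` observations)
    are dropped with a warning: their correlation is undefined.
    """
    if t.scale != "log2fc":
        raise ValueError("co-expression analysis expects a log2fc tensor")
    X = t.values.reshape(t.n_genes, -1)
    M = t.mask.reshape(t.n_genes, -1).astype(float)
    n_obs = M.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(M, X, 0.0).sum(axis=1) / n_obs
        var = np.where(M, (X - mean[:, None]) ** 2, 0.0).sum(axis=1)
    keep = (n_obs >= min_samples) & (var > 0)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} genes with undefined correlation "
            "(zero variance or too few observations)",
            stacklevel=2,
        )
    X, M = X[keep], M[keep]
    genes = tuple(g for g, k in zip(t.gene_ids, keep) if k)

    Xm = np.where(M.astype(bool), X, 0.0)
    n = M @ M.T
    Sx = Xm @ M.T
    Sxx = (Xm * Xm) @ M.T
    Sxy = Xm @ Xm.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / n
        varp = Sxx - Sx ** 2 / n
        r = cov / np.sqrt(varp * varp.T)
    r = np.where(np.isfinite(r), r, 0.0)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CoexpressionNetwork(genes=genes, cor=r)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over equal-width connectivity bins."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array([
        k[(k >= lo) & (k < hi)].mean() if c > 0 else np.nan
        for lo, hi, c in zip(edges[:-1], edges[1:], counts)
    ])
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    fit = linregress(np.log10(centers[ok]), np.log10(counts[ok] / counts.sum()))
    return float(fit.rvalue ** 2)


def pick_soft_threshold(
    net: CoexpressionNetwork,
    candidates: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> CoexpressionNetwork:
    """Choose the smallest power with scale-free fit R^2 >= ``r2_target``.

    Falls back to the argmax power (with a warning) if no candidate reaches
    the target, and to a fixed beta = 6 for networks too small to bin.
    """
    if net.n_genes < 30:
        warnings.warn(
            "fewer than 30 genes: connectivity binning unreliable, using beta = 6",
            stacklevel=2,
        )
        beta = 6
        adj = np.abs(net.cor) ** beta
        np.fill_diagonal(adj, 1.0)
        return CoexpressionNetwork(net.genes, net.cor, beta, adj, None,
                                   scale_free_fit(adj, n_bins))
    r2s = []
    for beta in candidates:
        adj = np.abs(net.cor) ** beta
        np.fill_diagonal(adj, 1.0)
        r2 = scale_free_fit(adj, n_bins)
        r2s.append(r2)
        if r2 >= r2_target:
            return CoexpressionNetwork(net.genes, net.cor, beta, adj, None, r2)
    best = int(np.argmax(r2s))
    beta = list(candidates)[best]
    warnings.warn(
        f"no power reached R^2 >= {r2_target}; using argmax beta = {beta} "
        f"(R^2 = {r2s[best]:.3f})",
        stacklevel=2,
    )
    adj = np.abs(net.cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return CoexpressionNetwork(net.genes, net.cor, beta, adj, None, r2s[best])


def tom_similarity(net: CoexpressionNetwork) -> CoexpressionNetwork:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbor adjacency, k_i is the connectivity; the
    diagonal is 1 by definition.
    """
    if net.adjacency is None:
        raise ValueError("adjacency not computed; run pick_soft_threshold first")
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return CoexpressionNetwork(net.genes, net.cor, net.beta, net.adjacency,
                               tom, net.sft_r2)


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 30,
    cut_quantile: float = 0.99,
) -> list[np.ndarray]:
    """Average-linkage clustering on 1 - TOM with a fixed-height cut.

    Groups smaller than ``min_size`` are merged into the group with the
    highest mean inter-group TOM.  Returns gene-index arrays.
    """
    if net.tom is None:
        raise ValueError("TOM not computed; run tom_similarity first")
    n = net.n_genes
    if n < 2:
        return [np.arange(n)]
    diss = 1.0 - net.tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = average(squareform(diss, checks=False))
    cut = float(np.quantile(Z[:, 2], cut_quantile))
    labels = fcluster(Z, t=cut, criterion="distance")

    groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    # merge undersized groups into their nearest group by mean TOM
    while len(groups) > 1:
        sizes = [len(g) for g in groups]
        small = [i for i, s in enumerate(sizes) if s < min_size]
        if not small:
            break
        i = min(small, key=lambda j: sizes[j])
        sims = [
            net.tom[np.ix_(groups[i], groups[j])].mean() if j != i else -np.inf
            for j in range(len(groups))
        ]
        j = int(np.argmax(sims))
        groups[j] = np.concatenate([groups[j], groups[i]])
        del groups[i]
    if len(groups) == 1 and n >= min_size:
        warnings.warn("all genes fell into a single group", stacklevel=2)
    return [np.sort(g) for g in groups]


# ---------------------------------------------------------------------------
# self-organizing map refinement
# ---------------------------------------------------------------------------

def _grid_shape(K: int) -> tuple[int, int]:
    """Near-square SOM grid with exactly K units (5 x 3 for K = 15)."""
    best = (K, 1)
    for r in range(1, int(np.sqrt(K)) + 1):
        if K % r == 0:
            best = (K // r, r)
    return best


def mean_trajectories(t: ExpressionTensor) -> np.ndarray:
    """Cross-patient mean log2fc per gene and time; unobserved times -> 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = t.masked().mean(axis=1)
    return np.ma.filled(m, 0.0)


def som_refine(
    t: ExpressionTensor,
    groups: list[np.ndarray],
    K: int,
    seed: int,
    *,
    epochs: int = 40,
    lr0: float = 0.5,
    lr_end: float = 0.01,
) -> ClusterAssignment:
    """Refine network groups with a K-unit self-organizing map.

    The codebook is seeded from the group centroids (cycled over the K units
    and padded with randomly drawn gene trajectories), then trained on the
    cross-patient mean trajectories with a Gaussian neighborhood whose
    radius, like the learning rate, decays linearly over a fixed number of
    epochs.  Each gene is assigned to its best-matching unit; empty units
    are dropped and the surviving count reported as K.
    """
    X = mean_trajectories(t)
    n_genes = X.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n_genes:
        raise ValueError("more SOM units than genes")
    rng = np.random.default_rng(seed)
    rows, cols = _grid_shape(K)
    # unit coordinates on the grid
    coords = np.array([(i, j) for i in range(rows) for j in range(cols)], float)

    # codebook: network-group centroids first, padded with random genes
    centroids = [X[g].mean(axis=0) for g in groups if len(g)]
    codebook = np.empty((K, X.shape[1]))
    n_init = min(len(centroids), K)
    for u in range(n_init):
        codebook[u] = centroids[u]
    if n_init < K:
        pad = rng.choice(n_genes, size=K - n_init, replace=K - n_init > n_genes)
        codebook[n_init:] = X[pad] + 0.01 * rng.standard_normal((K - n_init, X.shape[1]))

    radius0 = max(rows, cols) / 2.0
    radius_end = 0.5
    order = np.arange(n_genes)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr0 + (lr_end - lr0) * frac
        radius = radius0 + (radius_end - radius0) * frac
        rng.shuffle(order)
        for idx in order:
            x = X[idx]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * radius * radius))
            codebook += (lr * h)[:, None] * (x - codebook)

    bmus = np.array([
        int(np.argmin(((codebook - x) ** 2).sum(axis=1))) for x in X
    ])
    # drop empty units, relabel 1..K_surviving
    used = np.unique(bmus)
    relabel = {u: i + 1 for i, u in enumerate(used)}
    labels = np.array([relabel[b] for b in bmus])
    return ClusterAssignment(genes=t.gene_ids, labels=labels, K=len(used))


# ---------------------------------------------------------------------------
# cluster summaries
# ---------------------------------------------------------------------------

def cluster_profiles(t: ExpressionTensor, assign: ClusterAssignment) -> ClusterTrajectory:
    """Per-cluster mean and sample sd over member-gene log2fc values.

    Cells where no member gene is observed are masked; a singleton cluster
    has sd 0 at its observed cells.
    """
    if len(assign.genes) != t.n_genes:
        raise ValueError("assignment does not cover the tensor's genes")
    clusters = tuple(int(c) for c in np.unique(assign.labels))
    K = len(clusters)
    vals = np.zeros((K, t.n_patients, t.n_times))
    spread = np.zeros_like(vals)
    mask = np.zeros(vals.shape, dtype=bool)
    for ci, c in enumerate(clusters):
        idx = assign.members(c)
        sub = np.ma.MaskedArray(t.values[idx], mask=~t.mask[idx])
        n = sub.count(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = sub.mean(axis=0)
            sd = sub.std(axis=0, ddof=1)
        vals[ci] = np.ma.filled(mu, 0.0)
        sd = np.ma.filled(sd, 0.0)
        sd[n <= 1] = 0.0
        spread[ci] = sd
        mask[ci] = n > 0
    return ClusterTrajectory(vals, spread, mask, clusters, t.patient_ids)


def tag_modules(
    traj: ClusterTrajectory,
    grid: TimeGrid,
    *,
    early_h: float = 24.0,
    prolif_h: float = 240.0,
    late_h: float = 2190.0,
    sustained_frac: float = 0.5,
) -> tuple[dict[int, str], tuple[int, ...]]:
    """Tag clusters by peak timing of the cross-patient mean |log2fc|.

    peak <= 24 h -> early; 24 h < peak <= 240 h -> proliferation;
    peak > 2190 h, a late peak, or sustained elevation (>= half the peak at
    the last three points) -> long_term.  Flat clusters default to early and
    are flagged ambiguous.
    """
    hours = grid.hours_array
    module_map: dict[int, str] = {}
    ambiguous: list[int] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.ma.MaskedArray(traj.values, mask=~traj.mask).mean(axis=1)
    mean = np.abs(np.ma.filled(mean, 0.0))  # (K, T)
    for ci, c in enumerate(traj.cluster_ids):
        prof = mean[ci]
        peak = prof.max()
        if peak <= 0:
            module_map[c] = "early"
            ambiguous.append(c)
            continue
        t_peak = hours[int(np.argmax(prof))]
        sustained = np.all(prof[-3:] >= sustained_frac * peak)
        if t_peak > late_h or sustained:
            module_map[c] = "long_term"
        elif t_peak <= early_h:
            module_map[c] = "early"
        elif t_peak <= prolif_h:
            module_map[c] = "proliferation"
        else:
            module_map[c] = "long_term"  # late-peaking, closest phase
    return module_map, tuple(ambiguous)


def cluster_pipeline(
    t: ExpressionTensor,
    grid: TimeGrid,
    K: int,
    seed: int,
    *,
    min_size: int = 30,
    cut_quantile: float = 0.99,
) -> tuple[ClusterAssignment, ClusterTrajectory, CoexpressionNetwork]:
    """Network -> soft threshold -> TOM -> tree cut -> SOM -> profiles."""
    net = correlation_matrix(t)
    net = pick_soft_threshold(net)
    net = tom_similarity(net)
    groups = detect_modules(net, min_size=min_size, cut_quantile=cut_quantile)
    # restrict the tensor to the genes surviving correlation filtering
    if net.genes != t.gene_ids:
        keep = [t.gene_index(g) for g in net.genes]
        t = ExpressionTensor(
            t.values[keep], t.mask[keep], t.scale, net.genes, t.patient_ids
        )
    assign = som_refine(t, groups, K, seed)
    traj = cluster_profiles(t, assign)
    assign.module_map, assign.ambiguous = tag_modules(traj, grid)
    return assign, traj, net
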