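# Methods

`hepatwin` implements a patient-specific forecasting loop for liver
regeneration after partial hepatectomy (PHx), driven by longitudinal blood
gene expression. This note records the model, the defaults, and the design
choices, in the package's own terms.

## Data model

Expression is held as a dense gene × patient × time tensor with a boolean
observation mask and a scale tag. The legal scale order is enforced:
`raw → log1p → log2fc`, where `log1p` means `log2(1 + x)` and `log2fc` is
the difference from the patient's preoperative baseline on that scale. The
default sampling design is one preoperative baseline plus 14 post-operative
samples (5 min, 30 min, 1–4 h, 1–4 d, 10 d, 3/6/12 months; 1 month = 730 h),
but any grid with at least one pre-resection baseline and two post-operative
points is accepted.

## Preprocessing

1. **Imputation** fills a missing cell with the arithmetic mean of the other
   patients' observed values at the same gene and time point. No temporal
   interpolation is used: cross-patient averaging at a fixed time is the
   only defensible fill when the dynamics differ by orders of magnitude
   between hours and months. Cells observed in no patient stay masked and
   are reported.
2. **Negative correction** replaces negative values (noise artifacts of
   low-expressed genes) with the cross-patient mean of non-negative
   observations, falling back to 0 when none exists.
3. **Log transform**: `x → log2(1 + x)`.
4. **Baseline normalization** subtracts each patient's baseline per gene.
   A missing baseline masks the whole gene/patient series rather than being
   reconstructed from post-operative values, which would leak the response
   into its own reference.

All three cleaning steps are idempotent, and the scale tags make it
impossible to run them out of order.

**Gene selection.** A gene is kept when its cross-patient mean profile
sustains |log2fc| ≥ 1 (a two-fold change) at two or more *consecutive*
post-operative points, and is discarded as surgery-nonspecific when it
moves 1.5-fold or more at any pre-resection sample other than the baseline
(the signature of the abdominal incision rather than the liver resection).
The two-fold rule is evaluated on differences of `log2(1 + x)`, which
equals a true expression ratio of 2 only for large x; the approximation is
accepted and the thresholds are configurable (`preprocess` section of the
config). A per-patient variant of the rule (any single patient's profile
qualifying) is available behind the `per_patient` switch. Selection is
monotone in the threshold by construction.

## Temporal modules: co-expression network + SOM

The unsigned weighted network uses pairwise-complete Pearson correlation
over all observed (patient, time) samples, adjacency `|r|^β`, with β the
smallest power whose scale-free-topology fit reaches R² ≥ 0.8 (log–log
regression of the connectivity histogram over 10 equal-width bins; argmax
fallback with a warning, fixed β = 6 for networks under 30 genes where
binning is meaningless). An unsigned network is used deliberately: up- and
down-regulated genes sharing the same timing should co-cluster.

Topological overlap is
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_{u≠i,j} a_iu a_uj` and `k_i = Σ_{u≠i} a_iu`; the implementation
is vectorized and tested against a literal triple-loop oracle. Preliminary
groups come from average-linkage clustering on `1 − TOM` with a fixed-height
cut (default: the 0.99 quantile of merge heights) followed by merging of
groups below `min_module_size` (default 30) into the group with the highest
mean inter-group TOM. A fixed cut plus merge was chosen over adaptive
tree-cut heuristics because it is fully specifiable, configurable and easy
to test.

A K-unit self-organizing map (near-square grid, 5 × 3 for K = 15) then
refines the groups: the codebook is seeded from the group centroids padded
with randomly drawn gene trajectories, trained on cross-patient mean
trajectories for 40 epochs with a Gaussian neighborhood and linearly
decaying learning rate (0.5 → 0.01) and radius (half the grid → 0.5).
Genes are assigned to their best-matching unit; empty units are dropped, so
the reported K is the surviving count. SOM outcomes depend on the seed, so
seeds are explicit arguments everywhere and the same seed reproduces the
assignment exactly.

Cluster summaries are member-gene means and sample standard deviations per
patient and time (sd 0 for singletons, masked where no member is observed).
Clusters are tagged by the peak time of the cross-patient mean |log2fc|:
≤ 24 h → early response; ≤ 240 h → proliferation; later peaks or sustained
elevation over the last three samples (≥ half the peak) → long-term
recovery. Peaks between 10 days and 3 months are tagged long-term as the
closest phase. An all-zero cluster defaults to early and is flagged
ambiguous.

## The mechanistic regeneration model

Hepatocytes move between quiescent (Q), primed (P) and replicating (R)
states under a cytokine/growth-factor cascade; all species are
dimensionless with quiescent basal levels normalized to 1, time in hours:

    m      = M / (Q + P + R)                   metabolic load per hepatocyte
    TNF'   = κ_T m − λ_T TNF
    IL6'   = κ_I TNF − λ_I IL6
    STAT3' = κ_S IL6 / (1 + γ SOCS3) − λ_S STAT3
    SOCS3' = κ_C STAT3 − λ_C SOCS3
    IE'    = κ_E STAT3 − λ_E IE
    GF'    = κ_G m − λ_G GF − k_up ECM · GF
    ECM'   = k_syn − k_deg TNF · ECM
    Q'     = −α₀ (IE − IE_b)₊ Q + θ_R R + θ_P ECM · P
    P'     =  α₀ (IE − IE_b)₊ Q − β₀ GF · P − θ_P ECM · P − δ_P P
    R'     =  β₀ GF · P + k_div R − θ_R R − δ_R R

Resection removes a fraction f instantaneously (Q → (1−f)Q, P = R = 0,
molecular levels continuous), which raises m and launches the cascade: TNF
degrades the extracellular matrix (via MMPs) and induces IL-6; IL-6
activates STAT3; STAT3 transcribes SOCS3 (negative feedback) and
immediate-early genes; IE excess primes quiescent cells; free growth factor
drives P → R; the recovering ECM sequesters GF and reverts P → Q; R returns
to Q as the stimulus subsides. Liver volume is read out as
V = Q + h_P·P + h_R·R with h_P = h_R = 1.5, encoding hypertrophy of primed
and replicating cells.

**The priming threshold.** The Q → P flux uses the IE *excess* over its
basal level, `(IE − IE_b)₊`. With a mass-action term `α₀ IE Q` instead, the
positive basal IE (forced by the positive basal cascade that the ECM balance
requires) would drain Q indefinitely and no quiescent fixed point could
exist. Thresholding at the basal level makes the healthy liver an exact
fixed point of the system — the modelling statement that basal
immediate-early tone does not prime cells — at the cost of a
non-differentiable (but Lipschitz) right-hand side, which the LSODA
integrator handles without difficulty.

**Parameters.** Production/decay pairs are set so every basal level is
exactly 1 at m = 1 (e.g. κ_T = λ_T = 0.2 h⁻¹ gives TNF* = 1, and the basal
STAT3 solves a quadratic through the SOCS3 feedback). The transition rates
(α₀ = 0.05, β₀ = 0.02, θ_R = 0.1, θ_P = 0.05, k_div = 0.02, δ_P = δ_R =
0.001 h⁻¹) are a calibration of this package, fixed once so that
(i) the quiescent state is a stable fixed point, (ii) resections of 30–70%
recover volume to within 5% of normal within 12 months, and (iii) peak
replication falls in the 1–10-day proliferative window. Note that
`k_div < θ_R + δ_R` is required: otherwise the replicating pool grows
autonomously and the system has no homeostasis. These values carry no claim
of matching any experimentally fitted parameter set; they realize the
qualitative biology on the right time scales. All parameters round-trip
through JSON.

Integration uses stiff-capable LSODA at rtol 1e-8/atol 1e-10; undershoots
below −1e-9 trigger a warning before clipping at zero. The quiescent fixed
point is computed in closed form and polished by root-finding (residual
< 1e-8 enforced).

## Neural maps

Two small feed-forward regressions connect expression and model state:
forward (K clusters [+ resection fraction] → 10 state variables) and
reverse (state → clusters). Both are input → 64 → 128 → output with a
rectifier after each hidden layer and dropout p = 0.2 after each hidden
layer during training, trained on mean squared error with Adam
(lr 1e-3, 2000 epochs, full batch by default). The resection fraction is
injected as an extra forward-map input feature (default on) so
patient-specific surgery extent informs the inferred state. Inputs and
targets are standardized per feature with training-set statistics and
de-standardized at prediction; this stabilizes the loss across state
components whose magnitudes differ by an order of magnitude.

The implementation is plain numpy with analytic backpropagation (verified
against central finite differences to 1e-5 in the tests), fully seeded:
identical seed and data give bit-identical weights, and inference is
deterministic with dropout off. One map is trained across all time points
(pooled rows), not one per time point: with tens of usable samples per
patient, per-timepoint models would be absurdly under-determined.

Dropout biases the fitted function — empirically an inference-time MSE
floor of ≈ 0.02 on an exactly learnable task, independent of epochs and
learning rate. The exact-fit sanity check of the optimizer (identity task,
MSE < 0.01) therefore runs with dropout disabled; the production maps keep
dropout 0.2 as stated above.

## The twin loop and evaluation

For a patient with cluster expression `e₀` at an initial time point t0 and
resection fraction f: `state₀ = forward(e₀ [, f])`, clipped at 0. If t0 is
the preoperative baseline, the mapped state is pre-resection and the
resection is applied at hour 0 before integrating; for post-operative t0
(5 min, 30 min) the mapped state is already post-resection and integration
starts at t0's clock time. The reverse map then turns the simulated state
at every later grid point into predicted cluster expression. The twin
predicts cluster-level trajectories, not individual genes.

Forecasts are scored per cluster with MSE and Pearson r over observed
post-t0 points only; masked observations never enter any metric. Clusters
with fewer than two scored points or zero variance get an undefined-r flag
and are excluded from the correlation average (with a count reported).
The cohort split follows availability: patients ordered by descending
number of observed time points (ties broken by id), top two-thirds train,
bottom third test — the bottom third is exactly the group whose late
samples are missing, which is what makes them a meaningful forecasting
test.

## Synthetic cohorts

The generator emulates the study structure with full ground truth: 12
patients, resection fractions uniform on [0.5, 0.7], the 15-point grid,
K = 15 clusters of 40 genes. Each patient's mechanistic trajectory feeds a
known *truth map* `c(s) = amp ⊙ tanh(W (s − s_basal))` — affine in the
state deviation, squashed so the reverse network's nonlinearity is actually
exercised, exactly 0 at baseline. Member genes scatter as
`c_k(t)·(1 + a_g) + ε` with gene factors a_g ~ N(0, 0.1) and noise
ε ~ N(0, σ²), σ = 0.1 by default. Truth-map weights are drawn with scale
1.5/√10 so typical cluster excursions reach the two-fold magnitude that
defines the differentially expressed genes the generator emulates. The
missingness is block-structured: the last third of patients lose a growing
block (2, 3, 4, …) of late samples, reproducing the availability pattern
that motivates the train/test split. A raw-scale twin of the tensor
(inverted around per-gene baselines of 2^U(5,8)) exercises the full
preprocessing pipeline and round-trips to the log2fc tensor at machine
precision.

What the generator does *not* emulate: count-level RNA-seq noise
(library size, overdispersion), patient-specific kinetic parameters (all
virtual patients share the ODE constants; only f varies), gene-level
structure within clusters beyond a scale factor, and batch effects.
Passing tests therefore demonstrate the pipeline's internal consistency
and its ability to recover a known generative process of matching
structure — not performance on real donor data.

## Problem sizes and numerical choices

The test and acceptance workloads use the study-scale conditions directly
(12 patients × 15 time points × 600 genes; three seeded repeats of the
end-to-end run), which complete in tens of seconds. Correlation handles
missingness pairwise-complete; zero-variance genes are dropped with a
warning rather than propagating NaNs. Ties in module tagging (flat
clusters) default to early with an ambiguity flag. The fixed-height tree
cut, the SOM epoch count and the network training schedule are all exposed
in the config; none is adaptive, so every run is reproducible from its
seed.

## Known limitations

- The ODE instantiation realizes the interaction diagram qualitatively;
  rate constants are calibrated, not fitted to data.
- Cluster-level (not gene-level) prediction is a deliberate scope choice.
- The forward map extrapolates poorly outside the resection-fraction range
  seen in training; the synthetic default range is [0.5, 0.7].
- With strongly correlated clusters (all are functions of a 10-dimensional
  state), cluster-label recovery is not identifiable and is not claimed;
  the twin's accuracy is measured on the learned clusters, which is the
  quantity the forecasting task actually needs.
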