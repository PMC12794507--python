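# Methods

This note documents the models, defaults and numerical choices behind
`crossmod`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic cohort model

`synthgen.generate_cohort` draws counts gene-wise from a gamma-Poisson
(negative binomial) law: for gene *g* in cell *c*,

    x_gc ~ NB(mean = m_g · id_gc · mod_gc · b_gB · l_c,  dispersion θ)

with

* `m_g` — baseline mean, log-normal(loc −1, scale 1) across genes
  (PBMC-like: median below 1 count, a long tail of well-expressed genes);
* `id_gc` — `identity_strength` (default 5) when *g* belongs to the cell
  type's identity block, else 1; identity blocks are disjoint
  (`n_identity_genes` = 40 per type);
* `mod_gc = 1 + module_strength · a_c` for module genes, where the latent
  per-cell activity `a_c` is log-normal(0, `activity_sigma`) times the
  condition × timepoint multiplier `trend_effect` (applied to rejection
  donors only; default (1.0, 0.6, 0.6) plants a decline of module activity
  during rejection). The module is a *continuous* latent, not on/off, so
  score distributions have realistic spread;
* `b_gB` — per-gene multiplicative batch offset, log-normal(0,
  `batch_sigma` = 0.15). Batch effects are gene-wise multiplicative because
  the pipeline never integrates batches — it discovers programs per batch
  and matches them afterwards;
* `l_c` — log-normal library-size factor (`libsize_sigma` = 0.35);
* θ = `nb_dispersion` = 2 (variance = μ + μ²/θ).

`module_strength` = 6 and `activity_sigma` = 1.0 were fixed once so that
module genes are reliably overdispersed relative to the CV² curve and the
module program separates from identity programs in the factorization at the
benchmark sizes (hundreds of cells per batch); the source study reports no
effect sizes for its score differences, so these are the package's own
benchmark conditions, not an estimate of any cohort.

Cross-batch overlap: with `module_batch_overlap` = o < 1, every batch
expresses the full truth core (`n_module_genes`) plus batch-private extra
genes so the core is an o-fraction of each batch's active set. The truth
channel records the core (what a cross-batch intersection can recover), the
per-batch sets, and the per-cell latent activity.

**Independence nulls.** Library-size variation and batch offsets are
*shared* structure: even after CP10K normalization they leave a real mean
pairwise gene–gene correlation of about +0.01. Configurations that claim
"independently generated genes" (correlation-null calibration) therefore set
`libsize_sigma = 0` and `batch_sigma = 0`; with those, the measured null
mean correlation is −0.0002 at 2,000 genes × ~3,000 cells.

The generator does **not** simulate doublets, ambient RNA, mitochondrial
content, discrete sub-states, or any gene–gene correlation beyond the
planted programs. Passing tests therefore demonstrate that the pipeline's
statistics behave as specified under a clean negative-binomial world — not
that discovery is robust to real-data artifacts like ambient contamination
or annotation errors.

## Overdispersed gene selection

CV² = s²/x̄² per gene is regressed on 1/x̄ with a gamma-family GLM
(identity link), giving the fitted curve CV²(μ) = a₁/μ + α₀. A gene's
deviation is tested by the variance-ratio statistic
(n−1)·CV²_obs/CV²_fit ~ χ²(n−1), upper tail. On pure Poisson data
(CV² = 1/μ) this rejects at its nominal level (measured 5% ± 3% at
2,000 genes × 200 cells). If the fit degenerates (a₁ ≤ 0, e.g. constant or
collinear input) ranking falls back to the raw CV² residual with a warning.
Constant genes (CV² = 0) always rank last. Ties break lexicographically by
gene id so selection is deterministic.

## Consensus factorization

* Replicate fits: scikit-learn NMF, multiplicative updates, Frobenius
  objective, `init="random"`, `max_iter` 200, `tol` 1e−4, one child seed
  per replicate (spawned from the config seed; everything downstream is
  bit-reproducible given the seed). Input is per-gene unit-variance scaled
  *without centering*, preserving nonnegativity.
* Pooling and filtering: the R·K spectra are L2-normalized; each
  component's mean distance to its ⌈0.3·R⌉ nearest neighbors is computed
  and the least-dense `density_filter_quantile` = 0.25 fraction is
  discarded. (Discarding the *sparse* tail — rather than keeping only the
  densest quantile — is essential: keeping only the densest mode hides
  replicate disagreement and inflates stability for underfit K.)
* Consensus: k-means (10 restarts, seeded) on survivors; per-cluster
  component-wise median, re-normalized. If filtering leaves fewer than K
  components or an empty cluster, the filter is relaxed once, then the run
  errors. Fewer than R/2 converged replicates is an error.
* Stability is the mean silhouette of the survivor clustering. For K = 1
  the silhouette is undefined; the reported analog is the mean pairwise
  cosine similarity of survivors (1 exactly when all replicates agree).
* Usages are refit per cell by nonnegative least squares against the
  consensus spectra; error is ‖X − U·S‖_F on the scaled matrix.
* K selection: "minimum error and maximum stability" are rarely achieved by
  the same K, so the formal rule is: among K with error within 5% of the
  range minimum, maximize stability, ties toward smaller K. The full per-K
  table is always emitted so a scree-style visual choice remains possible.

## Cross-batch matching

Top-N genes per program (N = 200 by default, ties by gene id), Jaccard
distance 1 − |A∩B|/|A∪B|, average-linkage hierarchical clustering, tree cut
at distance 0.8. Linkage and cut height are package defaults (the
procedure's source leaves them unstated); both are configurable and a
fixed-cluster-count override (`n_clusters`) is available. Sensitivity: at
the benchmark scale, results are unchanged for cut heights 0.6–0.9, because
matching programs sit near distance ~0.2 and non-matching near ~1.0.
Clusters not covering every batch are dropped. Multiple programs of one
batch inside one cluster are unioned before the cross-batch intersection,
so a program split by one batch's factorization is not lost. The refined
gene set is the intersection of per-batch top-N lists; the scree table
(N vs intersection size) is emitted per cluster.

## Scoring

Single-cell: ranks of decreasing expression within each cell (average ranks
on ties), capped at `rmax` + 1 (`rmax` = 1500 by default, the source
method's convention; must be ≥ the signature size). U′ = Rs − n(n+1)/2,
score = 1 − U′/(n·rmax), clipped to [0, 1]. Signature genes absent from a
dataset are dropped (cross-species application); below 50% present is an
error. The score is invariant under any strictly monotone per-cell
transform, hence insensitive to depth normalization.

Bulk: per-gene z across samples (sd with ddof = 1), per-sample mean over
module genes; zero-variance genes are dropped with a warning.

## Validation statistics

* **Correlation null** — per cell type, mean pairwise Pearson r among
  module genes across cells, against `n_random` equal-size draws from
  expressed genes; empirical p uses the add-one estimator
  (1 + #{null ≥ obs})/(n_random + 1). Computed on log1p(CP10K) by default
  (see independence nulls above). Zero-variance genes are skipped within a
  draw.
* **Trend regression** — OLS of score on τ ∈ {0, 1, 2, …} per
  cell type × condition (the μ ∼ τ direction; a `reverse` flag fits τ ∼ μ —
  the reported sign is the same either way). Combinations with a single
  timepoint are omitted.
* **Permutation robustness** — per repetition an *independent* draw of
  `n_cells` per group without replacement; two-sided Wilcoxon rank-sum
  (normal approximation with tie correction — exact enumeration at n = 200
  is infeasible and unnecessary); BH across the `n_perm` p-values of one
  comparison (not across cell types); reported: proportion adjusted
  p < α. Degenerate corner: identical *constant* groups give raw p = 1
  everywhere; identical non-constant groups still produce differing
  subsamples, and the BH-controlled proportion stays ≤ 0.1%.
* **KS** — scipy two-sample D and asymptotic p.
* **Stratification** — 25th/75th percentile cut (type-7 linear
  interpolation), boundary ties to the lower stratum; pairwise two-sided
  Wilcoxon on the target gene between strata.
* **Gradient scan** — cells of each condition are randomly partitioned into
  `n_groups` pseudo-replicates (each ≥ `min_cells`, else an error stating
  the achievable group count); per gene, OLS of pseudo-replicate means on
  the condition code. The pseudo-replicates are random partitions, not
  individuals, so a random-intercept term would model pure noise; plain OLS
  on the pseudo-replicate means is used instead and is correctly calibrated
  under the null (measured 5% ± 2% at 500 genes).

## Enrichment and interactions

Fisher: two-sided exact p by the probability-ordering rule; odds ratio is
the sample cross-product, with Haldane 0.5 correction (and a flag) only
when a zero cell occurs. ORA: upper-tail hypergeometric per term, BH across
terms, FDR < 0.05 convention. GDA permutation: fraction of module genes
with ≥ 1 association vs equal-size random sets, add-one empirical p (never
exactly 0). Annotation content is always user-supplied.

Ligand–receptor pairing: both sides must pass the top-`expr_fraction`
mean-expression filter (ties at the cutoff included, zero-mean genes
excluded first) *and* a two-sided Wilcoxon (p < 0.05; t-test optional)
between groups. By default ligand and receptor must move in the same
direction (relaxable), reflecting the recruit-to-tissue reading of a
tissue ligand and a circulating receptor both rising with disease. Pairs
are ranked by the product of absolute rank-biserial effects — a package
choice; the source procedure only orders a diagram by expression.

## Classification

L2 logistic regression (C = 1, fixed for stability), repeated stratified
k-fold CV (5 × 10 by default). Standardization is fit on training folds
only. F1 (positive class = disease) and Cohen's κ are computed on pooled
out-of-fold predictions per repeat and averaged over repeats —
pooled-per-repeat is less biased for F1 than per-fold averaging at small
fold sizes. Groups with fewer than 2·k_folds samples are skipped with a
warning. Class balance is handled by stratification only; no loss
weighting.

## Problem sizes

The bundled demo and the test suite run scaled-down configurations chosen
as the package's benchmark sizes: cohorts of a few hundred to a few
thousand cells, 250–2,000 genes, 12–40 NMF replicates, K scans over ≤ 5
values. These sizes are where the planted-structure recovery checks were
calibrated (module recovery at Jaccard ≥ 0.95 across seeds; K_true = 5
recovered in 10/10 seeded runs at 600 cells, 40 replicates). Production
runs would use the conventional defaults (2,000 input genes, 200
replicates, K ∈ 7…14), which the config dataclasses carry.

## Known limitations

* Consensus NMF densifies the matrix; the sparse-capable container contract
  holds for I/O and subsetting, but factorization at >10⁵ cells would need
  chunked or sparse NMF.
* The activity-module picker (least between-cell-type score variation) is a
  heuristic; with several cross-type programs it returns only the flattest.
* The gradient scan assumes exchangeable cells within condition; real
  repeated-measures designs need donor-level modelling.
* Bulk and single-cell gene identifiers must match exactly
  (case-sensitive); no ortholog mapping is provided.
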