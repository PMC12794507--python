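# crossmod

Cross-batch gene-expression **module discovery and validation** for
single-cell and bulk transcriptomics.

## The problem

Multi-batch single-cell experiments (e.g. longitudinal PBMC profiling of
patient cohorts) contain two kinds of co-expressed gene programs: *identity*
programs that mark cell types, and *activity* programs expressed across cell
types that track cellular state — early activation, homing, stress response.
Activity programs are the interesting ones clinically, but they are subtle,
and naive batch integration can distort or erase them. `crossmod` follows
the opposite strategy: discover programs in **each batch independently**,
then keep only the programs that reproduce in **every** batch, and subject
the surviving consensus module to a battery of validation statistics.

The package is aimed at computational biologists who want this pipeline as
a tested, reusable library rather than a collection of notebook snippets.
Every stage runs on a bundled synthetic-data generator with a ground-truth
channel, so the whole pipeline is testable without any external download.

## The method

1. **Overdispersed gene selection.** Per gene, CV² = σ²/μ² is modelled as
   CV² = a₁/μ + α₀ (gamma GLM, identity link on 1/μ); genes are ranked by
   the upper-tail significance of their deviation from the fitted curve
   ((n−1)·CV²_obs/CV²_fit ~ χ²(n−1)).
2. **Consensus NMF per batch.** The cells × genes matrix (per-gene
   unit-variance scaled) is factorized X ≈ U·S (usages U ≥ 0, spectra
   S ≥ 0) R times with random restarts; the R·K unit-normalized spectra are
   pooled, low-density outlier components are discarded, survivors are
   k-means clustered into K consensus programs (component-wise medians).
   The mean silhouette of that clustering is the *stability*, the Frobenius
   residual after an NNLS usage refit is the *error*; K is chosen as the
   most stable K within 5% of the minimum error.
3. **Cross-batch consensus.** All programs are matched by the Jaccard
   similarity of their top-N gene lists (hierarchical clustering on
   1 − J); only clusters covering **all** batches are retained, and each
   retained cluster's gene set is the intersection of its per-batch top-N
   lists (with a scree table of intersection size vs N).
4. **Module scoring.** Per cell, the Mann–Whitney U construction on
   within-cell expression ranks: U′ = Rs − n(n+1)/2 over the signature's
   (capped) ranks, score = 1 − U′/(n·r_max) ∈ [0, 1]. Per bulk sample, the
   mean of cross-sample gene z-scores.
5. **Validation battery.** Random-gene-set correlation nulls, longitudinal
   trend regression (score ~ coded time per cell type × condition),
   permutation-resampling robustness (200-cell subsamples × 5,000
   repetitions, Wilcoxon + Benjamini–Hochberg), Kolmogorov–Smirnov
   comparisons, quartile stratification, a pseudo-replicate gradient scan,
   Fisher/hypergeometric enrichment, gene–disease-association permutation,
   ligand–receptor pairing, and logistic-regression disease classification
   (repeated stratified CV, F1 and Cohen's κ) against a CV²-matched control
   gene set.

## Worked example

The bundled demo config simulates a 3-batch cohort (5 cell types, a planted
40-gene activity module with 80% cross-batch overlap, a matched two-group
bulk dataset and annotation tables) and runs every stage:

```bash
crossmod run-all --config examples/config.yaml --outdir demo --seed 0
```

This takes ~10 s and writes one artifact directory per stage. With seed 0:

* `consensus/clusters.json` — six consensus clusters survive the all-batch
  filter; `consensus_2` has 40 genes and matches the planted module at
  Jaccard 1.00 (compare against `simulate/truth.json`).
* `score/activity_module.json` — `consensus_2` is flagged as the activity
  module (its score varies least between cell types relative to its total
  spread).
* `validate/trend_regression.tsv` — the planted decline of module activity
  under rejection is recovered, e.g. cell type CT0: β = −0.032 (p = 0.006)
  in rejection vs β = −0.003 (p = 0.81) in stable donors.
* `enrich/tf_enrichment.json` — the planted transcription-factor enrichment
  is detected: odds ratio 6.4, Fisher p = 8.6e−6 (2×2 table 14/26/26/309).
* `classify/classification.tsv` — module genes classify rejection vs stable
  bulk samples at F1 = 0.88 (κ = 0.77) vs F1 = 0.80 for the size-matched
  CV² control set.

Each stage can also be run individually (`crossmod simulate|discover|
consensus|score|validate|enrich|interact|classify`); stages communicate only
through on-disk artifacts (MTX + TSV sidecars, GMT, TSV, JSON), so any stage
can be re-run or swapped out in isolation. Real data enters through an
`input:` block (Matrix Market or TSV counts plus a cell-metadata table) in
place of `synthgen:`.

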