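"""Cohort-level validation statistics for module scores.

The battery that turns a discovered module into an evidenced one:

* ``correlation_null_test`` — is the module actually co-expressed?  Mean
  pairwise Pearson correlation per cell type against a random-gene-set null.
* ``trend_regression`` — does the score change over time?  OLS of the score
  on the coded timepoint, per cell type × condition.
* ``permutation_robustness`` — is a group difference robust to cell
  sampling?  Repeated equal-size subsampling + Wilcoxon + BH.
* ``ks_compare`` — distributional comparison of two score vectors.
* ``stratify_by_module`` — quartile stratification of bulk samples by module
  score and Wilcoxon on a target gene across strata.
* ``gradient_gene_scan`` — gene-wise linear gradients across ordered
  conditions using random pseudo-replicate groups of cells.

Every stochastic operation takes an explicit seed and records it in the
result it returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import CountMatrix, GeneSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation null
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNullResult:
    observed: pd.Series          # mean pairwise Pearson r per cell type
    null_mean: pd.Series         # per cell type, mean over random draws
    null_draws: pd.DataFrame     # cell types x n_random
    p_value: pd.Series           # empirical, add-one estimator
    n_random: int = 0
    seed: int = 0


def _normalize_log_cp10k(X: np.ndarray) -> np.ndarray:
    lib = X.sum(axis=0)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * 1e4)


def _mean_pairwise_r(X: np.ndarray) -> float:
    """Mean pairwise Pearson r among the rows of X (computed across cells).

    Zero-variance rows produce undefined correlations and are skipped.
    """
    sd = X.std(axis=1)
    X = X[sd > 0]
    if X.shape[0] < 2:
        return np.nan
    C = np.corrcoef(X)
    iu = np.triu_indices(C.shape[0], k=1)
    vals = C[iu]
    return float(np.nanmean(vals))


def correlation_null_test(counts: CountMatrix, gene_set: GeneSet,
                          n_random: int = 1000, seed: int = 0,
                          normalize: bool = True) -> CorrelationNullResult:
    """Mean pairwise module-gene correlation per cell type vs a random null.

    Per cell type, the observed statistic is the mean pairwise Pearson
    correlation (across cells) among the module genes; the null repeats the
    statistic for ``n_random`` equal-size random draws from the expressed
    genes.  The empirical p-value is ``(1 + #{null >= observed}) /
    (n_random + 1)``.  Expression is library-size normalized (log1p CP10K)
    by default so that shared depth variation does not masquerade as
    co-expression.
    """
    if len(gene_set) < 2:
        raise ValueError("gene set must contain >= 2 genes")
    rng = np.random.default_rng(seed)
    X = counts.dense()
    if normalize:
        X = _normalize_log_cp10k(X)
    meta = counts.cell_meta
    celltypes = sorted(meta["cell_type"].unique())
    expressed = np.flatnonzero(counts.gene_means() > 0)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    sig_idx = np.array([gene_pos[g] for g in gene_set.genes if g in gene_pos])
    n_draw = len(sig_idx)

    draws = np.array([
        rng.choice(expressed, n_draw, replace=False) for _ in range(n_random)
    ])

    observed, null_rows, pvals = {}, {}, {}
    for ct in celltypes:
        cells = np.flatnonzero((meta["cell_type"] == ct).to_numpy())
        if len(cells) < 3:
            raise ValueError(f"cell type {ct} has <3 cells")
        sub = X[:, cells]
        obs = _mean_pairwise_r(sub[sig_idx])
        null = np.array([_mean_pairwise_r(sub[d]) for d in draws])
        observed[ct] = obs
        null_rows[ct] = null
        pvals[ct] = (1 + np.sum(null >= obs)) / (n_random + 1)

    return CorrelationNullResult(
        observed=pd.Series(observed, name="observed_r"),
        null_mean=pd.Series({ct: np.nanmean(v) for ct, v in null_rows.items()},
                            name="null_mean_r"),
        null_draws=pd.DataFrame(null_rows).T,
        p_value=pd.Series(pvals, name="p"),
        n_random=n_random, seed=seed,
    )


# ---------------------------------------------------------------------------
# longitudinal trend regression
# ---------------------------------------------------------------------------

def trend_regression(scores: pd.Series, cell_meta: pd.DataFrame,
                     timepoint_order: list[str] | None = None,
                     reverse: bool = False) -> pd.DataFrame:
    """OLS slope of module score on coded time, per cell type × condition.

    Timepoints are coded 0, 1, 2, … in the given (or sorted) order; cells are
    the observations.  The default regresses score on time (μ ∼ τ);
    ``reverse=True`` fits time on score instead — the sign of the slope, the
    reported quantity, is shared by the two forms.  Combinations with fewer
    than two distinct timepoints are omitted with a warning.
    """
    meta = cell_meta.loc[scores.index]
    order = timepoint_order or sorted(meta["timepoint"].unique())
    tau_code = {tp: float(i) for i, tp in enumerate(order)}

    rows = []
    for (ct, cond), idx in meta.groupby(["cell_type", "condition"]).groups.items():
        y = scores.loc[idx].to_numpy()
        t = meta.loc[idx, "timepoint"].map(tau_code).to_numpy()
        if len(np.unique(t)) < 2:
            logger.warning("single timepoint for %s/%s; omitted", ct, cond)
            continue
        if reverse:
            res = scipy.stats.linregress(y, t)
        else:
            res = scipy.stats.linregress(t, y)
        rows.append({"cell_type": ct, "condition": cond,
                     "beta": res.slope, "p": res.pvalue, "n_cells": len(y)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation-resampling robustness
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Subsample 200 cells per group, 5000 times, Wilcoxon + BH at 0.05."""

    n_cells: int = 200
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class PermutationResult:
    proportion_significant: float
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    group_means: pd.DataFrame    # n_perm x 2
    config: PermutationConfig = field(default_factory=PermutationConfig)


def permutation_robustness(scores_a: pd.Series, scores_b: pd.Series,
                           config: PermutationConfig | None = None
                           ) -> PermutationResult:
    """Robustness of a two-group score difference to cell subsampling.

    Each repetition draws ``n_cells`` per group without replacement (fresh,
    independent draw every repetition), runs a two-sided Wilcoxon rank-sum
    test (normal approximation with tie correction) on the subsampled score
    vectors, then BH-adjusts across the ``n_perm`` p-values; the reported
    quantity is the proportion of repetitions with adjusted p < alpha.
    """
    config = config or PermutationConfig()
    config.validate()
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    for name, arr in (("A", a), ("B", b)):
        if len(arr) < config.n_cells:
            raise ValueError(
                f"group {name} has {len(arr)} cells, fewer than "
                f"n_cells={config.n_cells}"
            )
    rng = np.random.default_rng(config.seed)
    p_raw = np.empty(config.n_perm)
    means = np.empty((config.n_perm, 2))
    for i in range(config.n_perm):
        sa = a[rng.choice(len(a), config.n_cells, replace=False)]
        sb = b[rng.choice(len(b), config.n_cells, replace=False)]
        means[i] = sa.mean(), sb.mean()
        p_raw[i] = scipy.stats.mannwhitneyu(
            sa, sb, alternative="two-sided", method="asymptotic"
        ).pvalue
    reject, p_adj, _, _ = multipletests(p_raw, alpha=config.alpha,
                                        method="fdr_bh")
    return PermutationResult(
        proportion_significant=float(reject.mean()),
        p_raw=p_raw, p_adjusted=p_adj,
        group_means=pd.DataFrame(means, columns=["mean_a", "mean_b"]),
        config=config,
    )


# ---------------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    D: float
    p_value: float
    n_a: int
    n_b: int


def ks_compare(scores_a: pd.Series | np.ndarray,
               scores_b: pd.Series | np.ndarray) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison.

    D is the maximum vertical distance between the two empirical CDFs; the
    p-value is the asymptotic probability of a statistic at least as extreme
    under the null that both samples share one distribution.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return KSResult(D=float(res.statistic), p_value=float(res.pvalue),
                    n_a=len(a), n_b=len(b))


# ---------------------------------------------------------------------------
# quartile stratification
# ---------------------------------------------------------------------------

def stratify_by_module(bulk_scores: pd.Series, target_gene_expr: pd.Series
                       ) -> dict:
    """Stratify samples into low/mid/high module-score groups and compare.

    Strata are cut at the 25th/75th percentiles (linear interpolation,
    type-7 quantiles; boundary ties go to the lower stratum) and the target
    gene's expression is compared between each pair of strata with a
    two-sided Wilcoxon rank-sum test.
    """
    if len(bulk_scores) < 4:
        raise ValueError("stratification needs >= 4 samples")
    target = target_gene_expr.loc[bulk_scores.index]
    s = bulk_scores.to_numpy(dtype=float)
    q25, q75 = np.quantile(s, [0.25, 0.75])
    strata = np.where(s <= q25, "low", np.where(s <= q75, "mid", "high"))
    groups = {lab: target.to_numpy()[strata == lab]
              for lab in ("low", "mid", "high")}
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError(
            "empty stratum after quantile ties; more samples are needed"
        )
    comparisons = {}
    for g1, g2 in (("low", "mid"), ("mid", "high"), ("low", "high")):
        res = scipy.stats.mannwhitneyu(groups[g1], groups[g2],
                                       alternative="two-sided")
        comparisons[f"{g1}_vs_{g2}"] = {
            "p": float(res.pvalue),
            "mean_" + g1: float(groups[g1].mean()),
            "mean_" + g2: float(groups[g2].mean()),
        }
    return {
        "strata": pd.Series(strata, index=bulk_scores.index, name="stratum"),
        "sizes": {lab: int(len(v)) for lab, v in groups.items()},
        "comparisons": comparisons,
    }


# ---------------------------------------------------------------------------
# gradient gene scan
# ---------------------------------------------------------------------------

def gradient_gene_scan(counts: CountMatrix, condition_codes: pd.Series,
                       n_groups: int = 10, min_cells: int = 50,
                       seed: int = 0) -> pd.DataFrame:
    """Gene-wise linear gradients across ordered conditions.

    Within each condition, cells are randomly partitioned into ``n_groups``
    pseudo-replicates (each must hold at least ``min_cells`` cells); per gene
    the pseudo-replicate mean expressions are regressed on the condition code
    by OLS.  Returns one row per gene with slope, two-sided p and direction;
    the conventional significance threshold is p < 0.05.
    """
    codes = condition_codes.loc[counts.cell_ids]
    rng = np.random.default_rng(seed)
    X = counts.dense()

    rep_means, rep_codes = [], []
    for code in sorted(codes.unique()):
        cells = np.flatnonzero((codes == code).to_numpy())
        per_group = len(cells) // n_groups
        if per_group < min_cells:
            achievable = max(1, len(cells) // min_cells)
            raise ValueError(
                f"condition {code}: {len(cells)} cells / {n_groups} groups = "
                f"{per_group} per group < min_cells={min_cells}; at most "
                f"{achievable} groups are achievable"
            )
        perm = rng.permutation(cells)
        for g in range(n_groups):
            grp = perm[g * per_group:(g + 1) * per_group]
            rep_means.append(X[:, grp].mean(axis=1))
            rep_codes.append(float(code))

    M = np.vstack(rep_means)            # replicates x genes
    t = np.asarray(rep_codes)
    n = len(t)
    tc = t - t.mean()
    denom = float((tc ** 2).sum())
    slopes = tc @ (M - M.mean(axis=0)) / denom
    resid = M - M.mean(axis=0) - np.outer(tc, slopes)
    df = n - 2
    s2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(s2 / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slopes / se, 0.0)
    p = 2 * scipy.stats.t.sf(np.abs(tstat), df)
    return pd.DataFrame({
        "gene": counts.gene_ids,
        "slope": slopes,
        "p": p,
        "direction": np.where(slopes > 0, "up", np.where(slopes < 0, "down",
                                                         "flat")),
        "significant": p < 0.05,
    }).set_index("gene")
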