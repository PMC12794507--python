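"""Per-batch gene-expression-program discovery.

Pipeline stage one: select overdispersed genes by their squared coefficient
of variation (CV²) relative to a fitted CV² = a1/μ + α0 curve, then run
replicated non-negative matrix factorization and aggregate the replicate
components into consensus programs.  NMF is stochastic, so a single fit is
not reproducible; the consensus procedure pools the gene spectra of R
replicate fits, filters low-density (outlier) components, clusters the
survivors into K groups and takes the component-wise median of each cluster
as the consensus spectrum.  The mean silhouette of that clustering is the
*stability* of the factorization and the Frobenius norm of the residual
after refitting the cell usages is its *error*; both guide the choice of K.

Individual replicate fits use scikit-learn's multiplicative-update NMF
(Frobenius objective); everything around them — pooling, density filtering,
consensus, stability/error, K selection — lives here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .io_core import CountMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryConfig:
    """Parameters of the per-batch program discovery.

    Defaults follow the replicated-factorization convention: 2000
    overdispersed input genes, 200 NMF replicates, K explored from 7 to 14.
    ``density_filter_quantile`` is the fraction of pooled replicate
    components discarded as low-density outliers (those whose mean distance
    to their ``knn_fraction·R`` nearest neighbors falls in the top quantile).
    """

    n_top_genes: int = 2000
    n_replicates: int = 200
    k_range: tuple[int, ...] = tuple(range(7, 15))
    density_filter_quantile: float = 0.25
    knn_fraction: float = 0.3
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.k_range:
            raise ValueError("k_range must be nonempty")
        if min(self.k_range) < 2 and min(self.k_range) != 1:
            raise ValueError("k_range entries must be >= 1")
        if max(self.k_range) >= self.n_top_genes:
            raise ValueError("k_range must lie within [1, n_top_genes)")
        if not 0 < self.density_filter_quantile <= 1:
            raise ValueError("density_filter_quantile must be in (0, 1]")


@dataclass
class CV2Fit:
    """Fitted CV² = a1/μ + α0 curve with per-gene deviation significance."""

    a1: float
    alpha0: float
    mean: pd.Series
    cv2: pd.Series
    p_value: pd.Series         # upper-tail deviation from the fitted curve
    fallback: bool = False     # True when the GLM fit degenerated to residual ranking

    def fitted(self, mu: np.ndarray) -> np.ndarray:
        return self.a1 / np.asarray(mu) + self.alpha0


@dataclass
class ProgramSet:
    """Consensus factorization at one K for one batch."""

    K: int
    spectra: pd.DataFrame       # K x genes, rows unit L2 norm
    usages: pd.DataFrame        # cells x K, nonnegative
    stability: float
    error: float
    n_replicates_used: int = 0

    def top_genes(self, program: int, n: int) -> list[str]:
        """Top-n genes of one program by spectra weight, ties by gene id."""
        w = self.spectra.iloc[program]
        order = sorted(range(len(w)), key=lambda i: (-w.iloc[i], w.index[i]))
        return [w.index[i] for i in order[:n]]


# ---------------------------------------------------------------------------
# overdispersed gene selection
# ---------------------------------------------------------------------------

def fit_cv2(counts: CountMatrix) -> CV2Fit:
    """Fit the mean–CV² relation and score each gene's overdispersion.

    CV² = variance/mean² is modelled as ``a1/μ + α0`` by a gamma-family GLM
    with identity link on 1/μ.  A gene's deviation from the fitted curve is
    tested with a scaled chi-square on the variance ratio:
    ``(n-1)·CV²_obs/CV²_fit ~ χ²(n-1)`` under the curve, upper tail.  If the
    fit degenerates (a1 ≤ 0) genes are ranked by the raw CV² residual instead
    (``fallback=True``), with a warning.
    """
    X = counts.dense()
    n = counts.n_cells
    mu = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    expressed = mu > 0
    cv2 = np.full_like(mu, 0.0)
    cv2[expressed] = var[expressed] / mu[expressed] ** 2

    mu_fit = mu[expressed]
    cv2_fit_obs = cv2[expressed]
    fallback = False
    try:
        with warnings.catch_warnings():
            # identity link on Gamma is the intended (textbook) CV2 fit
            warnings.simplefilter("ignore")
            glm = sm.GLM(cv2_fit_obs, sm.add_constant(1.0 / mu_fit),
                         family=sm.families.Gamma(
                             link=sm.families.links.Identity()))
            res = glm.fit()
        alpha0, a1 = float(res.params[0]), float(res.params[1])
    except Exception:  # perfectly collinear / degenerate inputs
        alpha0, a1 = float(np.median(cv2_fit_obs)), -1.0
    if a1 <= 0 or not np.isfinite(a1) or np.any(a1 / mu_fit + alpha0 <= 0):
        warnings.warn(
            "degenerate CV2 fit (a1 <= 0); ranking by raw CV2 residual",
            stacklevel=2,
        )
        fallback = True
        a1, alpha0 = 0.0, max(float(np.median(cv2_fit_obs)), 1e-12)

    p = np.ones(len(mu))
    fitted_curve = np.where(expressed, a1 / np.where(expressed, mu, 1.0) + alpha0,
                            np.inf)
    ratio = np.zeros(len(mu))
    ratio[expressed] = cv2[expressed] / fitted_curve[expressed]
    if fallback:
        # pseudo p-values: monotone in the residual (ties share a rank),
        # for ranking only
        resid = cv2 - np.where(expressed, alpha0, np.inf)
        p = scipy.stats.rankdata(-resid, method="min") / (len(mu) + 1.0)
    else:
        p[expressed] = scipy.stats.chi2.sf((n - 1) * ratio[expressed], n - 1)

    idx = pd.Index(counts.gene_ids, name="gene")
    return CV2Fit(a1=a1, alpha0=alpha0,
                  mean=pd.Series(mu, index=idx),
                  cv2=pd.Series(cv2, index=idx),
                  p_value=pd.Series(p, index=idx),
                  fallback=fallback)


def select_overdispersed(counts: CountMatrix, n_top: int) -> tuple[GeneSet, CV2Fit]:
    """Return the ``n_top`` most overdispersed genes and the CV² fit.

    Genes are ranked by the upper-tail significance of their CV² deviation
    from the fitted curve; constant genes (zero variance) rank last and are
    never selected ahead of an expressed, variable gene.  Ties break
    lexicographically by gene id for determinism.
    """
    expressed = counts.gene_means() > 0
    n_expressed = int(expressed.sum())
    if n_top > n_expressed:
        raise ValueError(
            f"n_top={n_top} exceeds the {n_expressed} genes with nonzero mean"
        )
    fit = fit_cv2(counts)
    df = pd.DataFrame({
        "p": fit.p_value,
        "cv2": fit.cv2,
        "expressed": expressed,
    })
    df["rank_key"] = np.where(df["expressed"] & (df["cv2"] > 0), df["p"], 2.0)
    df = df.sort_values(["rank_key", "gene"], kind="mergesort")
    top = df.index[:n_top].tolist()
    return GeneSet("overdispersed", top), fit


# ---------------------------------------------------------------------------
# consensus NMF
# ---------------------------------------------------------------------------

def _scale_unit_variance(X: np.ndarray) -> np.ndarray:
    """Per-gene unit-variance scaling without centering (keeps nonnegativity)."""
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return X / sd


def _l2_normalize_rows(H: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(H, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return H / norms


def consensus_nmf(counts: CountMatrix, K: int,
                  config: DiscoveryConfig) -> ProgramSet:
    """Replicated NMF with consensus aggregation at a fixed K.

    The input matrix (already restricted to the selected genes) is scaled to
    unit per-gene variance; R replicate factorizations are fit with distinct
    seeds; all R·K unit-normalized gene spectra are pooled; components whose
    mean distance to their ``ceil(knn_fraction·R)`` nearest neighbors falls
    in the top ``density_filter_quantile`` fraction are discarded as
    low-density outliers; survivors are k-means
    clustered into K groups whose component-wise medians (re-normalized) are
    the consensus spectra.  Usages are refit by nonnegative least squares.
    """
    config.validate()
    Xs = _scale_unit_variance(counts.dense().T)  # cells x genes
    rng = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in rng.spawn(config.n_replicates + 1)]

    spectra_pool: list[np.ndarray] = []
    used = 0
    for r in range(config.n_replicates):
        model = NMF(n_components=K, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=config.max_iter,
                    tol=config.tol, random_state=child_seeds[r])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter reached is acceptable
            model.fit(Xs)
        H = model.components_
        if not np.all(np.isfinite(H)):
            warnings.warn(f"replicate {r} did not converge; dropped",
                          stacklevel=2)
            continue
        spectra_pool.append(_l2_normalize_rows(H))
        used += 1
    if used < config.n_replicates / 2:
        raise RuntimeError(
            f"only {used}/{config.n_replicates} NMF replicates converged"
        )

    pool = np.vstack(spectra_pool)  # (used*K) x genes
    survivors, labels = _filter_and_cluster(
        pool, K, used, config, kmeans_seed=child_seeds[-1]
    )

    consensus = np.vstack([
        np.median(survivors[labels == k], axis=0) for k in range(K)
    ])
    consensus = _l2_normalize_rows(consensus)

    stability = _clustering_stability(survivors, labels, K)

    usages = np.vstack([
        scipy.optimize.nnls(consensus.T, Xs[c])[0] for c in range(Xs.shape[0])
    ])
    error = float(np.linalg.norm(Xs - usages @ consensus))

    genes = pd.Index(counts.gene_ids, name="gene")
    programs = pd.Index([f"P{k}" for k in range(K)], name="program")
    return ProgramSet(
        K=K,
        spectra=pd.DataFrame(consensus, index=programs, columns=genes),
        usages=pd.DataFrame(usages, index=pd.Index(counts.cell_ids,
                                                   name="cell_id"),
                            columns=programs),
        stability=stability,
        error=error,
        n_replicates_used=used,
    )


def _filter_and_cluster(pool: np.ndarray, K: int, n_replicates: int,
                        config: DiscoveryConfig, kmeans_seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Local-density filtering then k-means; relaxes the filter once."""
    n_neighbors = max(1, int(np.ceil(config.knn_fraction * n_replicates)))
    n_neighbors = min(n_neighbors, pool.shape[0] - 1)
    dists = squareform(pdist(pool))
    np.fill_diagonal(dists, np.inf)
    knn_mean = np.sort(dists, axis=1)[:, :n_neighbors].mean(axis=1)

    for relax in (False, True):
        if relax:
            keep = np.ones(pool.shape[0], dtype=bool)
        else:
            threshold = np.quantile(knn_mean,
                                    1.0 - config.density_filter_quantile)
            keep = knn_mean <= threshold
        survivors = pool[keep]
        if survivors.shape[0] < K:
            if relax:
                raise RuntimeError(
                    f"fewer surviving components ({survivors.shape[0]}) than "
                    f"K={K} even without density filtering"
                )
            warnings.warn("density filter left fewer components than K; "
                          "relaxing the filter", stacklevel=2)
            continue
        km = KMeans(n_clusters=K, n_init=10, random_state=kmeans_seed)
        labels = km.fit_predict(survivors)
        if len(np.unique(labels)) == K:
            return survivors, labels
        if not relax:
            warnings.warn("empty consensus cluster; relaxing the density "
                          "filter", stacklevel=2)
    raise RuntimeError("consensus clustering failed to produce K clusters")


def _clustering_stability(survivors: np.ndarray, labels: np.ndarray,
                          K: int) -> float:
    """Mean silhouette of the replicate-component clustering.

    With a single program the silhouette is undefined; the natural analog is
    the mean pairwise cosine similarity of the (unit-norm) surviving
    components, which is 1 exactly when all replicates agree.
    """
    if K == 1 or len(np.unique(labels)) < 2:
        if survivors.shape[0] < 2:
            return 1.0
        sims = survivors @ survivors.T
        iu = np.triu_indices(survivors.shape[0], k=1)
        return float(np.clip(sims[iu].mean(), -1.0, 1.0))
    if survivors.shape[0] <= K:
        return 0.0
    return float(silhouette_score(survivors, labels))


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

def select_k(counts: CountMatrix, config: DiscoveryConfig
             ) -> tuple[int, pd.DataFrame, dict[int, ProgramSet]]:
    """Explore ``config.k_range`` and choose K by error and stability.

    "Minimum error and maximum stability" are not simultaneously achievable
    in general; the formal rule used here is: among the K whose error lies
    within 5% of the range minimum, pick the one with maximum stability,
    breaking ties toward smaller K.  The full per-K table is returned so the
    visual (scree) criterion can be applied instead.
    """
    config.validate()
    results: dict[int, ProgramSet] = {}
    rows = []
    for K in sorted(config.k_range):
        try:
            ps = consensus_nmf(counts, K, config)
        except RuntimeError as exc:
            logger.warning("K=%d degenerate: %s", K, exc)
            continue
        results[K] = ps
        rows.append({"K": K, "stability": ps.stability, "error": ps.error})
    if not results:
        raise RuntimeError("all K in k_range were degenerate")
    table = pd.DataFrame(rows).set_index("K")
    return choose_k_from_table(table), table, results


def choose_k_from_table(table: pd.DataFrame, error_band: float = 0.05) -> int:
    """The K-selection rule on a per-K (stability, error) table.

    Among the K whose error is within ``error_band`` of the minimum, the one
    with maximum stability wins; ties break toward smaller K.
    """
    band = table["error"] <= table["error"].min() * (1.0 + error_band)
    candidates = table[band].reset_index()
    candidates = candidates.sort_values(["stability", "K"],
                                        ascending=[False, True],
                                        kind="mergesort")
    return int(candidates["K"].iloc[0])


# ---------------------------------------------------------------------------
# reference multiplicative-update path (used by invariant tests)
# ---------------------------------------------------------------------------

def multiplicative_update_objectives(X: np.ndarray, K: int, n_iter: int,
                                     seed: int = 0) -> np.ndarray:
    """Frobenius objective trajectory of plain Lee–Seung updates.

    A minimal reference implementation of the multiplicative-update rule,
    independent of the fitting backend, exposing the per-iteration objective
    so its guaranteed monotone descent can be asserted.
    """
    rng = np.random.default_rng(seed)
    n, m = X.shape
    W = rng.random((n, K)) + 1e-3
    H = rng.random((K, m)) + 1e-3
    eps = 1e-12
    objectives = np.empty(n_iter)
    for it in range(n_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        objectives[it] = np.linalg.norm(X - W @ H)
    return objectives
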