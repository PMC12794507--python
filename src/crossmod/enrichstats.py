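"""Enrichment statistics over user-supplied annotation tables.

Three procedures: Fisher's exact test for a single category (e.g. is the
module enriched for transcription factors?), hypergeometric
over-representation analysis (ORA) with BH correction across many annotation
sets, and a permutation test for gene–disease associations (observed fraction
of module genes with at least one association vs equal-size random gene
sets).  The annotation *content* is always supplied by the user; only the
statistics live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import GeneSet


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple[int, int, int, int]  # (mod∩cat, mod∖cat, bg∩cat, rest)
    category: str
    haldane_corrected: bool = False


@dataclass
class GDAPermResult:
    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def fisher_enrichment(module: GeneSet, category: GeneSet,
                      background: GeneSet) -> EnrichmentResult:
    """Two-sided Fisher exact test of category membership in the module.

    The 2×2 table crosses module membership with category membership over
    the background; the odds ratio is the plain sample cross-product
    (Haldane 0.5 correction applied, and flagged, only when a zero cell
    occurs).  The p-value is the exact two-sided hypergeometric probability
    under the probability-ordering rule.
    """
    mod = module.as_set()
    bg = background.as_set()
    offenders = mod - bg
    if offenders:
        raise ValueError(
            f"module genes outside the background: {sorted(offenders)[:5]}"
        )
    cat = category.as_set() & bg
    a = len(mod & cat)
    b = len(mod - cat)
    c = len((bg - mod) & cat)
    d = len(bg - mod - cat)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = False
    if 0 in (a, b, c, d):
        haldane = True
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return EnrichmentResult(odds_ratio=float(orr), p_value=float(p),
                            table=(a, b, c, d), category=category.name,
                            haldane_corrected=haldane)


def ora(module: GeneSet, annotation_sets: list[GeneSet],
        background: GeneSet) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with BH correction.

    Per annotation term: k = module genes in the term, K = background genes
    in the term, n = module size, N = background size; upper-tail
    hypergeometric p, BH-adjusted across terms.  Terms disjoint from the
    background are skipped with a warning.  Convention: FDR < 0.05 is called
    significant.
    """
    if not annotation_sets:
        raise ValueError("at least one annotation set is required")
    mod = module.as_set()
    bg = background.as_set()
    if mod - bg:
        raise ValueError(
            f"module genes outside the background: {sorted(mod - bg)[:5]}"
        )
    N, n = len(bg), len(mod)
    rows = []
    for term in annotation_sets:
        term_bg = term.as_set() & bg
        if not term_bg:
            warnings.warn(f"annotation set {term.name!r} disjoint from the "
                          "background; skipped", stacklevel=2)
            continue
        K = len(term_bg)
        k = len(mod & term_bg)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term.name, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < 0.05
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def gda_permutation(module: GeneSet, gda_table: pd.DataFrame,
                    universe: GeneSet, n_perm: int = 1000,
                    seed: int = 0) -> GDAPermResult:
    """Permutation test of the fraction of module genes with an association.

    The observed fraction of module genes appearing at least once in the
    gene–disease table is compared to the same fraction in ``n_perm`` random
    equal-size gene sets drawn from the universe; empirical p uses the
    add-one estimator ``(1 + #{null >= observed}) / (n_perm + 1)`` and can
    therefore never be zero.
    """
    uni = universe.as_set()
    if not uni:
        raise ValueError("empty universe")
    mod = module.as_set()
    if mod - uni:
        raise ValueError(
            f"module genes outside the universe: {sorted(mod - uni)[:5]}"
        )
    associated = set(gda_table["gene"].astype(str))
    observed = len(mod & associated) / len(mod)

    rng = np.random.default_rng(seed)
    uni_list = sorted(uni)
    assoc_mask = np.array([g in associated for g in uni_list])
    null = np.array([
        assoc_mask[rng.choice(len(uni_list), len(mod), replace=False)].mean()
        for _ in range(n_perm)
    ])
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return GDAPermResult(observed_fraction=float(observed),
                         null_fractions=null, p_value=float(p),
                         n_perm=n_perm, seed=seed)
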