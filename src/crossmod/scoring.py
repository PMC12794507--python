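"""Module scoring: per-cell rank-based scores and per-sample bulk mean-z.

The single-cell score follows the Mann–Whitney U construction: within each
cell, all genes are ranked by decreasing expression (average ranks on ties,
ranks beyond ``rmax`` clamped to ``rmax + 1``), the rank-sum of the signature
genes gives U′ = Rs − n(n+1)/2, and the score is 1 − U′/(n·rmax), clipped to
[0, 1].  Being rank-based, the score is invariant to any strictly monotone
transform of a cell's expression vector, which makes it comparable across
cells with different sequencing depths and across normalization choices.

The bulk score is the per-sample mean of cross-sample gene z-scores of the
module genes (unbounded, "mean-z" units).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import CountMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ScoreParams:
    """Rank-score parameters; ``rmax`` bounds the considered ranks."""

    rmax: int = 1500

    def validate(self, signature_size: int) -> None:
        if self.rmax < signature_size:
            raise ValueError(
                f"rmax={self.rmax} smaller than signature size {signature_size}"
            )


def ucell_score(counts: CountMatrix, gene_set: GeneSet,
                params: ScoreParams | None = None,
                min_fraction_present: float = 0.5) -> pd.Series:
    """Per-cell rank-based module score in [0, 1].

    Signature genes absent from the dataset are dropped (the signature may
    come from another species); fewer than ``min_fraction_present`` of them
    present is an error listing the missing genes.
    """
    params = params or ScoreParams()
    universe = set(counts.gene_ids)
    present = [g for g in gene_set.genes if g in universe]
    missing = [g for g in gene_set.genes if g not in universe]
    if not gene_set.genes:
        raise ValueError("empty gene set")
    frac = len(present) / len(gene_set.genes)
    logger.info("signature %s: %d/%d genes present", gene_set.name,
                len(present), len(gene_set.genes))
    if frac < min_fraction_present:
        raise ValueError(
            f"only {len(present)}/{len(gene_set.genes)} signature genes present "
            f"(<{min_fraction_present:.0%}); missing: {missing}"
        )
    params.validate(len(present))

    X = counts.dense()  # genes x cells
    sig_idx = counts.gene_index(present)
    n = len(present)
    rmax = params.rmax
    scores = np.empty(counts.n_cells)
    # rank genes by decreasing expression within each cell, average ties
    for start in range(0, counts.n_cells, 2048):
        block = X[:, start:start + 2048]
        ranks = scipy.stats.rankdata(-block, axis=0, method="average")
        ranks = np.minimum(ranks, rmax + 1)
        rs = ranks[sig_idx, :].sum(axis=0)
        u = rs - n * (n + 1) / 2.0
        scores[start:start + block.shape[1]] = 1.0 - u / (n * rmax)
    scores = np.clip(scores, 0.0, 1.0)
    out = pd.Series(scores, index=pd.Index(counts.cell_ids, name="cell_id"),
                    name=f"{gene_set.name}_score")
    out.attrs.update({"unit": "ucell", "gene_set": gene_set.name,
                      "rmax": rmax, "n_genes_used": n})
    return out


def bulk_module_score(bulk: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample mean of cross-sample z-scores of the module genes.

    ``bulk`` is genes × samples.  Genes with zero cross-sample SD carry no
    ranking information and are dropped with a warning; all module genes
    degenerate (or fewer than two samples) is an error.
    """
    if bulk.shape[1] < 2:
        raise ValueError("bulk_module_score needs >= 2 samples")
    present = [g for g in gene_set.genes if g in bulk.index]
    if not present:
        raise ValueError("no module genes present in the bulk matrix")
    sub = bulk.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all module genes have zero cross-sample variance")
    if (~usable).any():
        warnings.warn(
            f"dropped {int((~usable).sum())} zero-variance module genes",
            stacklevel=2,
        )
    sub = sub.loc[usable]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[usable], axis=0)
    out = z.mean(axis=0)
    out.name = f"{gene_set.name}_meanz"
    out.index.name = "sample_id"
    out.attrs.update({"unit": "mean_z", "gene_set": gene_set.name,
                      "n_genes_used": int(usable.sum())})
    return out
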