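"""Ligand–receptor pairing between bulk tissue and circulating cells.

Links tissue-expressed signalling genes (ligands, from a two-group bulk
dataset) to receptors on circulating cell types (from single-cell data)
through a user-supplied interaction table.  A gene qualifies on either side
only if it sits in the top expressed fraction of its compartment *and*
differs between the phenotype/condition groups (two-sided Wilcoxon, p<0.05,
by default moving the same way on both sides).  Qualifying pairs of the
requested interaction category are ranked by the product of the absolute
rank-biserial effect sizes of the two differential tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import CountMatrix, GeneSet


@dataclass
class LRConfig:
    expr_fraction: float = 0.5
    category_filter: str = "cytokine"
    top_pairs_per_celltype: int = 5
    p_threshold: float = 0.05
    test: str = "wilcoxon"          # or "ttest"
    require_same_direction: bool = True

    def validate(self) -> None:
        if not 0 < self.expr_fraction <= 1:
            raise ValueError("expr_fraction must be in (0, 1]")
        if self.test not in ("wilcoxon", "ttest"):
            raise ValueError("test must be 'wilcoxon' or 'ttest'")


def filter_expressed(matrix: pd.DataFrame, groups: pd.Series,
                     expr_fraction: float = 0.5) -> dict[str, GeneSet]:
    """Per group, the top expressed fraction of genes by mean expression.

    Zero-mean genes are excluded first; the top ``ceil(fraction·n_expressed)``
    genes are retained, with all genes tied at the cutoff value included (so
    the set can exceed the nominal size).  An all-zero group yields an empty
    set with a warning.
    """
    out: dict[str, GeneSet] = {}
    groups = groups.loc[matrix.columns]
    for g in sorted(groups.unique()):
        sub = matrix.loc[:, (groups == g).to_numpy()]
        means = sub.mean(axis=1)
        means = means[means > 0]
        if means.empty:
            warnings.warn(f"group {g!r} has no expressed genes", stacklevel=2)
            out[g] = GeneSet(str(g), [])
            continue
        k = int(np.ceil(expr_fraction * len(means)))
        ranked = means.sort_values(ascending=False, kind="mergesort")
        cutoff = ranked.iloc[k - 1]
        keep = ranked[ranked >= cutoff].index.tolist()
        out[g] = GeneSet(str(g), keep)
    return out


def _differential(values_a: np.ndarray, values_b: np.ndarray,
                  test: str) -> tuple[float, float]:
    """Two-sided test of a vs b; returns (p, signed rank-biserial effect).

    Positive effect means higher in group b (the "rejection" side by
    convention).
    """
    n1, n2 = len(values_a), len(values_b)
    if test == "ttest":
        res = scipy.stats.ttest_ind(values_b, values_a, equal_var=False)
        d = (values_b.mean() - values_a.mean())
        pooled = np.sqrt((values_a.var(ddof=1) + values_b.var(ddof=1)) / 2)
        effect = d / pooled if pooled > 0 else 0.0
        return float(res.pvalue), float(effect)
    res = scipy.stats.mannwhitneyu(values_b, values_a,
                                   alternative="two-sided")
    effect = 2.0 * res.statistic / (n1 * n2) - 1.0  # rank-biserial
    return float(res.pvalue), float(effect)


def pair_ligand_receptor(
    bulk: pd.DataFrame, phenotypes: pd.Series,
    sc_counts: CountMatrix, interaction_table: pd.DataFrame,
    config: LRConfig | None = None,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Rank ligand–receptor pairs linking tissue to circulating cell types.

    Ligands must pass :func:`filter_expressed` on the bulk matrix (in at
    least one phenotype group) and differ between the two phenotype groups;
    receptors must pass the same expression filter within a cell type and
    differ between the two single-cell condition groups.  Candidates are
    joined on the interaction table restricted to ``category_filter`` and the
    ``top_pairs_per_celltype`` best pairs per cell type are returned.
    """
    config = config or LRConfig()
    config.validate()
    for col in ("ligand", "receptor", "category"):
        if col not in interaction_table.columns:
            raise ValueError(f"interaction table lacks column {col!r}")
    table = interaction_table[
        interaction_table["category"] == config.category_filter
    ]
    if table.empty:
        available = sorted(interaction_table["category"].unique())
        raise ValueError(
            f"category {config.category_filter!r} absent from the interaction "
            f"table; available: {available}"
        )

    # --- ligand side (bulk) ---
    phen = phenotypes.loc[bulk.columns]
    groups = sorted(phen.unique())
    if len(groups) != 2:
        raise ValueError("exactly two phenotype groups are required")
    ref = reference_group if reference_group is not None else groups[0]
    alt = [g for g in groups if g != ref][0]
    bulk_sets = filter_expressed(bulk, phen, config.expr_fraction)
    bulk_expressed = set().union(*(s.as_set() for s in bulk_sets.values()))
    ligand_stats: dict[str, tuple[float, float]] = {}
    for gene in sorted(set(table["ligand"]) & bulk_expressed & set(bulk.index)):
        va = bulk.loc[gene, (phen == ref).to_numpy()].to_numpy(dtype=float)
        vb = bulk.loc[gene, (phen == alt).to_numpy()].to_numpy(dtype=float)
        p, eff = _differential(va, vb, config.test)
        if p < config.p_threshold:
            ligand_stats[gene] = (p, eff)

    # --- receptor side (single cell, per cell type) ---
    meta = sc_counts.cell_meta
    sc_conditions = sorted(meta["condition"].unique())
    if len(sc_conditions) != 2:
        raise ValueError("single-cell data must have exactly two conditions")
    sc_ref, sc_alt = sc_conditions[0], sc_conditions[1]
    if reference_group is not None and reference_group in sc_conditions:
        sc_ref = reference_group
        sc_alt = [c for c in sc_conditions if c != sc_ref][0]

    X = sc_counts.dense()
    gene_pos = {g: i for i, g in enumerate(sc_counts.gene_ids)}
    rows = []
    for ct in sorted(meta["cell_type"].unique()):
        in_ct = (meta["cell_type"] == ct).to_numpy()
        ct_df = pd.DataFrame(X[:, in_ct], index=sc_counts.gene_ids)
        ct_groups = pd.Series(["all"] * int(in_ct.sum()),
                              index=ct_df.columns)
        expressed = filter_expressed(ct_df, ct_groups,
                                     config.expr_fraction)["all"].as_set()
        cond = meta.loc[in_ct, "condition"].to_numpy()
        for _, row in table.iterrows():
            lig, rec = str(row["ligand"]), str(row["receptor"])
            if lig not in ligand_stats or rec not in expressed:
                continue
            ri = gene_pos.get(rec)
            if ri is None:
                continue
            va = X[ri, in_ct][cond == sc_ref]
            vb = X[ri, in_ct][cond == sc_alt]
            p, eff = _differential(va, vb, config.test)
            if p >= config.p_threshold:
                continue
            lig_p, lig_eff = ligand_stats[lig]
            if config.require_same_direction and lig_eff * eff <= 0:
                continue
            rows.append({
                "cell_type": ct, "ligand": lig, "receptor": rec,
                "ligand_p": lig_p, "ligand_effect": lig_eff,
                "receptor_p": p, "receptor_effect": eff,
                "rank_score": abs(lig_eff) * abs(eff),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["cell_type", "ligand", "receptor",
                                     "ligand_p", "ligand_effect",
                                     "receptor_p", "receptor_effect",
                                     "rank_score"])
    out = out.sort_values(["cell_type", "rank_score"],
                          ascending=[True, False], kind="mergesort")
    out = out.groupby("cell_type", group_keys=False).head(
        config.top_pairs_per_celltype
    )
    return out.reset_index(drop=True)
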