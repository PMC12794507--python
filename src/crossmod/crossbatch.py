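"""Cross-batch program matching and consensus gene-set refinement.

Programs discovered independently in each batch are matched by the Jaccard
similarity of their top-N gene lists: all programs are collated, pairwise
Jaccard distances (1 − similarity) feed an agglomerative clustering, the tree
is cut, and only clusters whose members cover *every* batch are retained —
a program that cannot be found in all batches is not reproducible.  The
retained cluster's consensus gene set is the intersection of the per-batch
top-N lists, with a scree table (input N vs intersection size) emitted so the
choice of N can be judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .discovery import ProgramSet
from .io_core import GeneSet


@dataclass
class ConsensusConfig:
    """Cross-batch matching parameters.

    ``cut_height`` is a Jaccard *distance*: programs closer than it are
    merged.  ``n_clusters`` overrides the height-based cut with a fixed
    cluster count when set.
    """

    top_n: int = 200
    linkage: str = "average"
    cut_height: float = 0.8
    n_grid: tuple[int, ...] = tuple(range(50, 401, 50))
    n_clusters: int | None = None

    def validate(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")


@dataclass
class ConsensusCluster:
    """One matched cross-batch program cluster."""

    members: list[tuple[str, int]]          # (batch id, program index)
    top_genes: dict[str, list[str]]         # per batch: union of member top-N
    ranked_genes: dict[str, list[str]]      # per batch: full ranked union list
    batches_covered: set[str] = field(default_factory=set)
    gene_set: GeneSet | None = None
    scree: pd.DataFrame | None = None


def jaccard(a: GeneSet | set, b: GeneSet | set) -> float:
    """|a ∩ b| / |a ∪ b|; defined as 0 when both sets are empty."""
    sa = a.as_set() if isinstance(a, GeneSet) else set(a)
    sb = b.as_set() if isinstance(b, GeneSet) else set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def match_programs(program_sets: dict[str, ProgramSet],
                   config: ConsensusConfig) -> list[ConsensusCluster]:
    """Match programs across batches by Jaccard clustering.

    Takes the top ``config.top_n`` genes of every program (ties broken by
    gene id), hierarchically clusters all programs on Jaccard distance, cuts
    the tree at ``cut_height`` (or into ``n_clusters`` groups) and keeps the
    clusters represented in all batches.  Multiple programs of one batch
    inside a cluster have their top-N lists unioned before the cross-batch
    intersection.  Output order, membership and gene sets are invariant to
    batch ordering and to program order within a batch.
    """
    config.validate()
    if len(program_sets) < 2:
        raise ValueError("match_programs needs programs from >= 2 batches")
    all_batches = sorted(program_sets)

    entries: list[tuple[str, int, list[str]]] = []
    for batch in all_batches:
        ps = program_sets[batch]
        for k in range(ps.K):
            entries.append((batch, k, ps.top_genes(k, config.top_n)))

    n = len(entries)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard(set(entries[i][2]), set(entries[j][2]))
            dist[i, j] = dist[j, i] = d
    Z = sch.linkage(squareform(dist, checks=False), method=config.linkage)
    if config.n_clusters is not None:
        labels = sch.fcluster(Z, t=config.n_clusters, criterion="maxclust")
    else:
        labels = sch.fcluster(Z, t=config.cut_height, criterion="distance")

    clusters: list[ConsensusCluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members = [(entries[i][0], entries[i][1]) for i in idx]
        covered = {b for b, _ in members}
        if covered != set(all_batches):
            continue
        cluster = ConsensusCluster(
            members=sorted(members),
            top_genes={}, ranked_genes={}, batches_covered=covered,
        )
        for batch in all_batches:
            programs = [k for b, k in members if b == batch]
            cluster.top_genes[batch] = _union_ordered(
                [entries_lookup(entries, batch, k) for k in programs]
            )
            ps = program_sets[batch]
            cluster.ranked_genes[batch] = _union_ranked(ps, programs)
        cluster.gene_set, cluster.scree = refine_gene_set(cluster, config)
        clusters.append(cluster)
    if not clusters:
        warnings.warn("no cluster covers all batches; returning empty list",
                      stacklevel=2)
    # deterministic output order: by (first member batch, program)
    clusters.sort(key=lambda c: c.members[0])
    for i, c in enumerate(clusters):
        if c.gene_set is not None:
            c.gene_set.name = f"consensus_{i}"
    return clusters


def entries_lookup(entries: list[tuple[str, int, list[str]]], batch: str,
                   k: int) -> list[str]:
    for b, kk, genes in entries:
        if b == batch and kk == k:
            return genes
    raise KeyError((batch, k))


def _union_ordered(lists: list[list[str]]) -> list[str]:
    seen: dict[str, None] = {}
    for lst in lists:
        for g in lst:
            seen.setdefault(g)
    return list(seen)


def _union_ranked(ps: ProgramSet, programs: list[int]) -> list[str]:
    """Full gene ranking for a batch: genes ordered by their best (max)
    spectra weight over the cluster's member programs, ties by gene id."""
    w = ps.spectra.iloc[programs].max(axis=0)
    order = sorted(range(len(w)), key=lambda i: (-w.iloc[i], w.index[i]))
    return [w.index[i] for i in order]


def refine_gene_set(cluster: ConsensusCluster,
                    config: ConsensusConfig) -> tuple[GeneSet, pd.DataFrame]:
    """Intersection of per-batch top-N lists plus the scree table.

    For every N in ``config.n_grid`` the intersection of the per-batch top-N
    ranked lists is computed; the final gene set uses ``config.top_n``.
    Requires a cluster covering all batches.
    """
    if not cluster.ranked_genes:
        raise ValueError("cluster has no per-batch gene rankings")
    batches = sorted(cluster.ranked_genes)

    def intersection_at(n: int) -> list[str]:
        sets = [set(cluster.ranked_genes[b][:n]) for b in batches]
        inter = set.intersection(*sets)
        # stable order: by rank in the first batch
        first = cluster.ranked_genes[batches[0]]
        return [g for g in first[:n] if g in inter]

    rows = [{"n_input": n, "n_intersection": len(intersection_at(n))}
            for n in sorted(set(config.n_grid) | {config.top_n})]
    scree = pd.DataFrame(rows).set_index("n_input")
    final = intersection_at(config.top_n)
    return GeneSet("consensus", final), scree


def jaccard_matrix(program_sets: dict[str, ProgramSet],
                   top_n: int = 200) -> pd.DataFrame:
    """Pairwise Jaccard similarity of all programs (heatmap-ready table)."""
    names, sets = [], []
    for batch in sorted(program_sets):
        ps = program_sets[batch]
        for k in range(ps.K):
            names.append(f"{batch}:P{k}")
            sets.append(set(ps.top_genes(k, top_n)))
    mat = np.array([[jaccard(a, b) for b in sets] for a in sets])
    return pd.DataFrame(mat, index=names, columns=names)
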