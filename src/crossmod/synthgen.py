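"""Synthetic single-cell cohorts, bulk datasets and annotation tables.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without external downloads:

* a multi-batch single-cell cohort of negative-binomial (gamma-Poisson)
  counts with per-cell library-size variation, one identity gene program per
  cell type, and one shared "activity" module expressed across cell types
  whose per-cell latent intensity is log-normal and modulated by
  condition × timepoint;
* a two-group bulk dataset (Gaussian on the log scale) in which module genes
  shift with the disease group and one ligand gene tracks the per-sample
  latent module score;
* annotation tables (transcription-factor list, gene–disease associations,
  ligand–receptor pairs) with optional planted enrichment of the module.

Every generator is deterministic given its config seed and carries a *truth*
channel (planted gene sets and latent activities) for parameter-recovery
tests.  Batch effects are multiplicative gene-wise offsets because the
pipeline analyzes batches independently and only matches programs afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import CountMatrix, GeneSet


class ConfigError(ValueError):
    """Raised when a generator config violates one of its invariants."""


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


@dataclass
class CohortConfig:
    """Design of a synthetic multi-batch single-cell cohort.

    ``trend_effect`` multiplies the module-gene activity of *rejection*
    donors at each timepoint (stable donors stay at 1.0); the default
    ``(1.0, 0.6, 0.6)`` plants the decline of the activity module during
    rejection that the longitudinal regression should detect.
    ``identity_strength`` / ``module_strength`` of 0 turn the respective
    effect off, leaving independently generated genes.
    """

    n_batches: int = 3
    n_celltypes: int = 5
    n_cells_per_type_per_donor: int = 50
    n_genes: int = 2000
    n_module_genes: int = 61
    n_donors_per_condition: int = 1   # per batch
    n_identity_genes: int = 40        # per cell type
    timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    conditions: tuple[str, ...] = ("stable", "rejection")
    trend_effect: tuple[float, ...] = (1.0, 0.6, 0.6)
    identity_strength: float = 5.0    # fold change of identity genes in their type
    module_strength: float = 6.0      # scale of the module activity effect
    activity_sigma: float = 1.0       # log-normal sd of the per-cell latent activity
    module_batch_overlap: float = 1.0 # fraction of a batch's module set shared by all
    nb_dispersion: float = 2.0        # gamma shape; var = mu + mu^2/dispersion
    libsize_sigma: float = 0.35       # log-normal library-size spread
    batch_sigma: float = 0.15         # log-normal per-gene batch offset spread
    mean_log_loc: float = -1.0        # baseline gene mean, log scale
    mean_log_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_batches", "n_celltypes", "n_cells_per_type_per_donor",
                     "n_genes", "n_module_genes", "n_donors_per_condition",
                     "n_identity_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_module_genes >= self.n_genes:
            raise ConfigError("n_module_genes must be smaller than n_genes")
        if len(self.trend_effect) != len(self.timepoints):
            raise ConfigError(
                "trend_effect length must equal the number of timepoints "
                f"({len(self.trend_effect)} vs {len(self.timepoints)})"
            )
        if not 0.0 < self.module_batch_overlap <= 1.0:
            raise ConfigError("module_batch_overlap must be in (0, 1]")
        needed = (self.n_celltypes * self.n_identity_genes + self.n_module_genes)
        if self.module_batch_overlap < 1.0:
            extras = int(round(self.n_module_genes
                               * (1.0 / self.module_batch_overlap - 1.0)))
            needed += self.n_batches * extras
        if needed > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for the planted structure "
                f"({needed} program genes required)"
            )
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")


@dataclass
class SyntheticCohort:
    """Generated counts plus the ground truth the generator planted."""

    counts: CountMatrix
    truth: dict = field(default_factory=dict)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a multi-batch cohort of NB counts with planted programs.

    Per gene g and cell c the count is NB with mean
    ``base_g · identity_gc · module_gc · batchoffset_gb · lib_c`` where
    ``module_gc = 1 + module_strength · a_c`` for module genes active in the
    cell's batch, ``a_c`` log-normal scaled by the condition × timepoint
    trend multiplier.  The truth channel records all planted sets and the
    per-cell latent activity ``module_strength · a_c``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    # planted gene sets: disjoint identity blocks, then the module core,
    # then per-batch module extras when overlap < 1
    cursor = 0
    identity_sets: dict[str, list[str]] = {}
    celltypes = [f"CT{i}" for i in range(config.n_celltypes)]
    for ct in celltypes:
        identity_sets[ct] = genes[cursor:cursor + config.n_identity_genes]
        cursor += config.n_identity_genes
    module_core = genes[cursor:cursor + config.n_module_genes]
    cursor += config.n_module_genes
    module_by_batch: dict[str, list[str]] = {}
    batches = [f"B{i}" for i in range(config.n_batches)]
    if config.module_batch_overlap < 1.0:
        n_extra = int(round(config.n_module_genes
                            * (1.0 / config.module_batch_overlap - 1.0)))
    else:
        n_extra = 0
    for b in batches:
        extras = genes[cursor:cursor + n_extra]
        cursor += n_extra
        module_by_batch[b] = module_core + extras

    base_mean = rng.lognormal(config.mean_log_loc, config.mean_log_scale,
                              config.n_genes)
    batch_offsets = {
        b: rng.lognormal(0.0, config.batch_sigma, config.n_genes) for b in batches
    }

    gene_pos = {g: i for i, g in enumerate(genes)}
    identity_idx = {ct: np.array([gene_pos[g] for g in gs])
                    for ct, gs in identity_sets.items()}
    module_idx_by_batch = {b: np.array([gene_pos[g] for g in gs])
                           for b, gs in module_by_batch.items()}

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    activities: list[float] = []
    trend = dict(zip(config.timepoints, config.trend_effect))
    cell_counter = 0
    for b in batches:
        for cond in config.conditions:
            for d in range(config.n_donors_per_condition):
                donor = f"{b}_{cond}_D{d}"
                for tp in config.timepoints:
                    mult = trend[tp] if cond == "rejection" else 1.0
                    for ct in celltypes:
                        n = config.n_cells_per_type_per_donor
                        mu = np.tile(base_mean * batch_offsets[b],
                                     (n, 1))  # cells x genes
                        if config.identity_strength > 0:
                            mu[:, identity_idx[ct]] *= config.identity_strength
                        a = rng.lognormal(0.0, config.activity_sigma, n) * mult
                        if config.module_strength > 0:
                            factor = 1.0 + config.module_strength * a
                            mu[:, module_idx_by_batch[b]] *= factor[:, None]
                        lib = rng.lognormal(0.0, config.libsize_sigma, n)
                        mu *= lib[:, None]
                        # gamma-Poisson: var = mu + mu^2 / dispersion
                        lam = rng.gamma(config.nb_dispersion,
                                        mu / config.nb_dispersion)
                        blocks.append(rng.poisson(lam).astype(float))
                        activities.extend(config.module_strength * a)
                        for _ in range(n):
                            meta_rows.append({
                                "cell_id": f"cell{cell_counter:06d}",
                                "batch": b, "donor": donor, "timepoint": tp,
                                "condition": cond, "cell_type": ct,
                            })
                            cell_counter += 1

    counts = np.vstack(blocks).T  # genes x cells
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    cm = CountMatrix(counts, genes, list(meta.index), meta)
    truth = {
        "identity_gene_sets": identity_sets,
        "module_genes": module_core,
        "module_genes_by_batch": module_by_batch,
        "cell_activity": pd.Series(np.asarray(activities), index=cm.cell_ids,
                                   name="true_activity"),
    }
    return SyntheticCohort(cm, truth)


# ---------------------------------------------------------------------------
# bulk generator
# ---------------------------------------------------------------------------

@dataclass
class BulkConfig:
    """Two-group bulk expression with a module shift and a tracking ligand."""

    n_samples_per_group: int = 50
    groups: tuple[str, str] = ("stable", "rejection")
    n_genes: int = 1000
    n_module_genes: int = 61
    module_genes: tuple[str, ...] | None = None  # overrides the default block
    module_shift: float = 1.0     # mean shift (log-scale z units) in rejection
    ligand_gene: str = "LIGAND0"  # CXCL12 analog, appended to the gene universe
    ligand_beta: float = 1.0      # slope of ligand on the latent module score
    activity_sd: float = 0.5      # sd of the per-sample latent module score
    noise_sigma: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 4:
            raise ConfigError(
                "n_samples_per_group must be >= 4 (quartile stratification)"
            )
        if self.n_module_genes >= self.n_genes:
            raise ConfigError("n_module_genes must be smaller than n_genes")
        if len(self.groups) != 2:
            raise ConfigError("exactly two groups required")


def generate_bulk(config: BulkConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a genes × samples bulk matrix with phenotypes and truth.

    Expression is Gaussian on the log scale.  Module genes carry the
    per-sample latent score ``s_j = module_shift·[group==rejection] + u_j``;
    the ligand gene is ``alpha + ligand_beta·s_j + noise`` so its expression
    tracks the module score across samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes) + [config.ligand_gene]
    if config.module_genes is not None:
        module_genes = [str(g) for g in config.module_genes]
        unknown = set(module_genes) - set(genes)
        if unknown:
            raise ConfigError(
                f"module genes outside the bulk universe: {sorted(unknown)[:3]}"
            )
    else:
        module_genes = _gene_ids(config.n_genes)[: config.n_module_genes]
    n = config.n_samples_per_group
    sample_ids = [f"S{g}_{i}" for g in config.groups for i in range(n)]
    group = np.repeat(list(config.groups), n)

    latent = rng.normal(0.0, config.activity_sd, 2 * n)
    score = latent + config.module_shift * (group == config.groups[1])

    baseline = rng.normal(5.0, 1.0, config.n_genes + 1)
    expr = (baseline[:, None]
            + rng.normal(0.0, config.noise_sigma,
                         (config.n_genes + 1, 2 * n)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    module_idx = np.array([gene_pos[g] for g in module_genes])
    expr[module_idx] += score[None, :]
    expr[-1] = baseline[-1] + config.ligand_beta * score + rng.normal(
        0.0, config.noise_sigma, 2 * n)

    matrix = pd.DataFrame(expr, index=genes, columns=sample_ids)
    phenotype = pd.DataFrame({"group": group},
                             index=pd.Index(sample_ids, name="sample_id"))
    truth = {
        "module_genes": module_genes,
        "ligand_gene": config.ligand_gene,
        "sample_score": pd.Series(score, index=sample_ids, name="true_score"),
    }
    return matrix, phenotype, truth


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def generate_annotations(
    n_genes: int,
    tf_fraction: float = 0.1,
    gda_fraction: float = 0.2,
    n_lr_pairs: int = 20,
    seed: int = 0,
    module_genes: Sequence[str] | None = None,
    tf_odds_ratio: float | None = None,
    gda_odds_ratio: float | None = None,
    n_disease_terms: int = 5,
) -> dict:
    """Generate TF list, gene–disease table and ligand–receptor table.

    When ``module_genes`` and a target odds ratio are given, the module is
    enriched for the annotation so that the realized 2×2 cross-product OR is
    close to the request; an infeasible request (more enriched genes than the
    module or the background can hold) raises :class:`ConfigError`.
    """
    if not 0 < tf_fraction < 1 or not 0 < gda_fraction < 1:
        raise ConfigError("tf_fraction and gda_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    module = [str(g) for g in module_genes] if module_genes is not None else []
    unknown = set(module) - set(genes)
    if unknown:
        raise ConfigError(f"module genes outside universe: {sorted(unknown)[:3]}")

    tf_genes = _annotated_subset(rng, genes, module, tf_fraction, tf_odds_ratio)
    gda_genes = _annotated_subset(rng, genes, module, gda_fraction, gda_odds_ratio)

    terms = [f"disease_{i}" for i in range(n_disease_terms)]
    gda_table = pd.DataFrame({
        "gene": gda_genes,
        "disease": rng.choice(terms, len(gda_genes)),
    })

    ligands = rng.choice(genes, n_lr_pairs, replace=False)
    receptors = rng.choice([g for g in genes if g not in set(ligands)],
                           n_lr_pairs, replace=False)
    categories = rng.choice(["cytokine", "other"], n_lr_pairs)
    lr_table = pd.DataFrame({
        "ligand": ligands, "receptor": receptors, "category": categories,
    })
    return {"tf_genes": tf_genes, "gda_table": gda_table, "lr_table": lr_table}


def _annotated_subset(
    rng: np.random.Generator,
    genes: list[str],
    module: list[str],
    fraction: float,
    odds_ratio: float | None,
) -> list[str]:
    """Pick annotated genes, optionally at a target OR for the module."""
    n = len(genes)
    if not module or odds_ratio is None:
        k = int(round(fraction * n))
        return sorted(rng.choice(genes, k, replace=False).tolist())
    m = len(module)
    bg = [g for g in genes if g not in set(module)]
    n_bg_hits = int(round(fraction * len(bg)))
    # solve the cross-product OR for the module hit count k:
    # (k/(m-k)) / (bg_hits/(bg_size-bg_hits)) = OR
    odds_bg = n_bg_hits / (len(bg) - n_bg_hits)
    k = int(round(m * odds_ratio * odds_bg / (1.0 + odds_ratio * odds_bg)))
    if k <= 0 or k >= m:
        raise ConfigError(
            f"requested odds ratio {odds_ratio} infeasible for module size {m} "
            f"and background fraction {fraction}"
        )
    hits = rng.choice(module, k, replace=False).tolist()
    hits += rng.choice(bg, n_bg_hits, replace=False).tolist()
    return sorted(hits)


def truth_module_gene_set(cohort: SyntheticCohort) -> GeneSet:
    """Convenience accessor for the planted activity module as a GeneSet."""
    return GeneSet("planted_module", cohort.truth["module_genes"])
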