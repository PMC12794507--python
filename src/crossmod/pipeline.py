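"""End-to-end pipeline orchestration.

Runs the stages simulate → discover → consensus → score → validate → enrich
→ interact → classify from a single YAML config.  Stages communicate only
via on-disk artifacts (MTX/TSV/GMT/JSON) so that any stage can be re-run or
replaced in isolation; each stage directory carries a ``provenance.json``
with the config hash, seed and package version, and a ``FAILED`` marker is
left behind when a stage raises.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVPlan, compare_feature_sets, cv2_select
from .cohortstats import (PermutationConfig, correlation_null_test, ks_compare,
                          permutation_robustness, stratify_by_module,
                          trend_regression)
from .crossbatch import ConsensusConfig, jaccard_matrix, match_programs
from .discovery import DiscoveryConfig, ProgramSet, select_k, select_overdispersed
from .enrichstats import fisher_enrichment, gda_permutation, ora
from .interactions import LRConfig, pair_ligand_receptor
from .io_core import (CountMatrix, GeneSet, read_count_matrix, read_gene_sets,
                      write_count_matrix, write_gene_sets, write_json)
from .scoring import ScoreParams, bulk_module_score, ucell_score
from .synthgen import BulkConfig, CohortConfig, generate_annotations, generate_bulk, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "discover", "consensus", "score", "validate",
          "enrich", "interact", "classify")


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if "seed" not in config:
        raise PipelineError("config must set a global seed")
    has_synth = "synthgen" in config
    has_input = "input" in config
    if has_synth == has_input:
        raise PipelineError(
            "config must set exactly one of 'synthgen' or 'input'"
        )
    if "interact" in config.get("stages", STAGES):
        if not has_synth and "interaction_table" not in config.get("input", {}):
            raise PipelineError(
                "interactions stage enabled but no interaction table "
                "configured"
            )


def _provenance(config: dict, stage: str) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "stage": stage,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.get("seed"),
        "crossmod_version": __version__,
    }


def run_pipeline(config: dict, outdir: str | Path,
                 stages: tuple[str, ...] | None = None) -> Path:
    """Execute the requested stages; returns the report directory."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages or config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")

    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        failed_marker = stage_dir / "FAILED"
        try:
            _STAGE_FUNCS[stage](config, outdir, state)
            write_json(_provenance(config, stage), stage_dir / "provenance.json")
            if failed_marker.exists():
                failed_marker.unlink()
        except Exception as exc:
            failed_marker.write_text(
                f"{type(exc).__name__}: {exc}\n{traceback.format_exc()}"
            )
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _get_counts(config: dict, outdir: Path, state: dict) -> CountMatrix:
    if "counts" in state:
        return state["counts"]
    mtx = outdir / "simulate" / "matrix.mtx"
    if mtx.exists():
        state["counts"] = read_count_matrix(mtx, "mtx")
    elif "input" in config:
        spec = config["input"]
        state["counts"] = read_count_matrix(
            spec["counts"], spec.get("format", "mtx"),
            meta_path=spec.get("metadata"),
        )
    else:
        raise PipelineError("no count matrix available; run 'simulate' first")
    return state["counts"]


def _stage_simulate(config: dict, outdir: Path, state: dict) -> None:
    block = config["synthgen"]
    seed = config["seed"]
    cohort_cfg = CohortConfig(**{**block.get("cohort", {}), "seed": seed})
    cohort = generate_cohort(cohort_cfg)
    stage_dir = outdir / "simulate"
    write_count_matrix(cohort.counts, stage_dir, "mtx")
    truth = {
        "identity_gene_sets": cohort.truth["identity_gene_sets"],
        "module_genes": cohort.truth["module_genes"],
        "module_genes_by_batch": cohort.truth["module_genes_by_batch"],
    }
    write_json(truth, stage_dir / "truth.json")
    cohort.truth["cell_activity"].to_csv(stage_dir / "truth_activity.tsv",
                                         sep="\t")
    state["counts"] = cohort.counts
    state["truth"] = cohort.truth

    bulk_cfg = BulkConfig(**{
        "n_genes": cohort_cfg.n_genes,
        "module_genes": tuple(cohort.truth["module_genes"]),
        **block.get("bulk", {}), "seed": seed + 1,
    })
    bulk, phenotype, bulk_truth = generate_bulk(bulk_cfg)
    bulk.to_csv(stage_dir / "bulk.tsv", sep="\t")
    phenotype.to_csv(stage_dir / "phenotype.tsv", sep="\t")
    state.update({"bulk": bulk, "phenotype": phenotype,
                  "bulk_truth": bulk_truth, "bulk_config": bulk_cfg})

    ann_cfg = block.get("annotations", {})
    ann = generate_annotations(
        n_genes=cohort_cfg.n_genes,
        module_genes=cohort.truth["module_genes"],
        seed=seed + 2, **ann_cfg,
    )
    pd.Series(ann["tf_genes"], name="gene").to_csv(
        stage_dir / "tf_genes.tsv", sep="\t", index=False)
    ann["gda_table"].to_csv(stage_dir / "gda.tsv", sep="\t", index=False)
    ann["lr_table"].to_csv(stage_dir / "lr_pairs.tsv", sep="\t", index=False)
    state["annotations"] = ann


def _stage_discover(config: dict, outdir: Path, state: dict) -> None:
    counts = _get_counts(config, outdir, state)
    block = config.get("discovery", {})
    seed = config["seed"]
    stage_dir = outdir / "discover"
    program_sets: dict[str, ProgramSet] = {}
    backgrounds: dict[str, list[str]] = {}
    tables = {}
    for i, batch in enumerate(sorted(counts.cell_meta["batch"].unique())):
        sub = counts.subset_cells(
            (counts.cell_meta["batch"] == batch).to_numpy())
        cfg = DiscoveryConfig(**{**block, "seed": seed + 10 + i})
        top, _ = select_overdispersed(sub, cfg.n_top_genes)
        backgrounds[batch] = top.genes
        restricted = sub.subset_genes(top.genes)
        best_k, table, results = select_k(restricted, cfg)
        ps = results[best_k]
        program_sets[batch] = ps
        tables[batch] = table
        ps.spectra.to_csv(stage_dir / f"{batch}_spectra.tsv", sep="\t")
        ps.usages.to_csv(stage_dir / f"{batch}_usages.tsv", sep="\t")
        table.to_csv(stage_dir / f"{batch}_k_table.tsv", sep="\t")
        write_json({"batch": batch, "chosen_K": best_k,
                    "stability": ps.stability, "error": ps.error,
                    "n_replicates_used": ps.n_replicates_used},
                   stage_dir / f"{batch}_metrics.json")
    write_gene_sets(
        [GeneSet(f"background_{b}", g) for b, g in backgrounds.items()],
        stage_dir / "backgrounds.gmt",
    )
    state["program_sets"] = program_sets
    state["backgrounds"] = backgrounds


def _load_program_sets(outdir: Path, state: dict) -> dict[str, ProgramSet]:
    if "program_sets" in state:
        return state["program_sets"]
    stage_dir = outdir / "discover"
    program_sets = {}
    for spectra_file in sorted(stage_dir.glob("*_spectra.tsv")):
        batch = spectra_file.name.rsplit("_spectra.tsv", 1)[0]
        spectra = pd.read_csv(spectra_file, sep="\t", index_col=0)
        usages = pd.read_csv(stage_dir / f"{batch}_usages.tsv", sep="\t",
                             index_col=0)
        metrics = json.loads(
            (stage_dir / f"{batch}_metrics.json").read_text())
        program_sets[batch] = ProgramSet(
            K=len(spectra), spectra=spectra, usages=usages,
            stability=metrics["stability"], error=metrics["error"],
        )
    if not program_sets:
        raise PipelineError("no discovery artifacts; run 'discover' first")
    state["program_sets"] = program_sets
    return program_sets


def _stage_consensus(config: dict, outdir: Path, state: dict) -> None:
    program_sets = _load_program_sets(outdir, state)
    cfg = ConsensusConfig(**config.get("consensus", {}))
    clusters = match_programs(program_sets, cfg)
    stage_dir = outdir / "consensus"
    write_gene_sets([c.gene_set for c in clusters if c.gene_set is not None],
                    stage_dir / "modules.gmt")
    jaccard_matrix(program_sets, cfg.top_n).to_csv(
        stage_dir / "jaccard_matrix.tsv", sep="\t")
    summary = []
    for c in clusters:
        c.scree.to_csv(stage_dir / f"{c.gene_set.name}_scree.tsv", sep="\t")
        summary.append({
            "name": c.gene_set.name,
            "members": [f"{b}:P{k}" for b, k in c.members],
            "n_genes": len(c.gene_set),
        })
    write_json(summary, stage_dir / "clusters.json")
    state["modules"] = [c.gene_set for c in clusters]


def _load_modules(outdir: Path, state: dict) -> list[GeneSet]:
    if "modules" not in state:
        path = outdir / "consensus" / "modules.gmt"
        if not path.exists():
            raise PipelineError("no consensus modules; run 'consensus' first")
        state["modules"] = read_gene_sets(path)
    return state["modules"]


def _pick_activity_module(counts: CountMatrix,
                          modules: list[GeneSet]) -> GeneSet:
    """The cross-cell-type (activity) module: the one whose score varies
    least between cell types relative to its overall spread."""
    if len(modules) == 1:
        return modules[0]
    meta = counts.cell_meta
    best, best_ratio = modules[0], np.inf
    for gs in modules:
        try:
            sc = ucell_score(counts, gs)
        except ValueError:
            continue
        overall = sc.std()
        between = sc.groupby(meta["cell_type"]).mean().std()
        ratio = between / overall if overall > 0 else np.inf
        if ratio < best_ratio:
            best, best_ratio = gs, ratio
    return best


def _stage_score(config: dict, outdir: Path, state: dict) -> None:
    counts = _get_counts(config, outdir, state)
    modules = _load_modules(outdir, state)
    params = ScoreParams(**config.get("scoring", {}))
    stage_dir = outdir / "score"
    scores = {}
    for gs in modules:
        try:
            scores[gs.name] = ucell_score(counts, gs, params)
        except ValueError as exc:
            logger.warning("module %s not scored: %s", gs.name, exc)
    df = pd.DataFrame(scores)
    df = counts.cell_meta.join(df)
    df.to_csv(stage_dir / "cell_scores.tsv", sep="\t")
    state["cell_scores"] = df
    activity = _pick_activity_module(counts, modules)
    state["activity_module"] = activity
    write_json({"activity_module": activity.name,
                "n_genes": len(activity)}, stage_dir / "activity_module.json")


def _require(state: dict, key: str, hint: str):
    if key not in state:
        raise PipelineError(f"missing {key!r}; run {hint} first in this "
                            "invocation (stages share artifacts on disk, but "
                            f"{key} is loaded from them)")
    return state[key]


def _stage_validate(config: dict, outdir: Path, state: dict) -> None:
    counts = _get_counts(config, outdir, state)
    modules = _load_modules(outdir, state)
    block = config.get("cohortstats", {})
    seed = config["seed"]
    stage_dir = outdir / "validate"
    if "cell_scores" not in state:
        _stage_score(config, outdir, state)
    scores_df = state["cell_scores"]
    activity = state["activity_module"]
    score = scores_df[activity.name]

    corr = correlation_null_test(
        counts, activity, n_random=block.get("n_random", 1000),
        seed=seed + 20,
    )
    pd.DataFrame({"observed_r": corr.observed, "null_mean_r": corr.null_mean,
                  "p": corr.p_value}).to_csv(
        stage_dir / "correlation_null.tsv", sep="\t")

    trends = trend_regression(score, counts.cell_meta)
    trends.to_csv(stage_dir / "trend_regression.tsv", sep="\t", index=False)

    meta = counts.cell_meta
    conditions = sorted(meta["condition"].unique())
    perm_summary = {}
    if len(conditions) == 2:
        a = score[meta["condition"] == conditions[0]]
        b = score[meta["condition"] == conditions[1]]
        pcfg = PermutationConfig(
            **{**block.get("permutation", {}), "seed": seed + 21})
        if min(len(a), len(b)) >= pcfg.n_cells:
            perm = permutation_robustness(a, b, pcfg)
            perm_summary = {
                "groups": conditions,
                "proportion_significant": perm.proportion_significant,
                "n_cells": pcfg.n_cells, "n_perm": pcfg.n_perm,
                "seed": pcfg.seed,
            }
        ks = ks_compare(a, b)
        perm_summary["ks"] = {"D": ks.D, "p": ks.p_value}
    write_json(perm_summary, stage_dir / "robustness.json")

    if "bulk" in state or (outdir / "simulate" / "bulk.tsv").exists():
        bulk = state.get("bulk")
        if bulk is None:
            bulk = pd.read_csv(outdir / "simulate" / "bulk.tsv", sep="\t",
                               index_col=0)
        bscore = bulk_module_score(bulk, activity)
        bscore.to_csv(stage_dir / "bulk_scores.tsv", sep="\t")
        ligand = config.get("synthgen", {}).get("bulk", {}).get(
            "ligand_gene", BulkConfig().ligand_gene)
        if ligand in bulk.index:
            strat = stratify_by_module(bscore, bulk.loc[ligand])
            write_json({"sizes": strat["sizes"],
                        "comparisons": strat["comparisons"]},
                       stage_dir / "stratification.json")


def _stage_enrich(config: dict, outdir: Path, state: dict) -> None:
    modules = _load_modules(outdir, state)
    counts = _get_counts(config, outdir, state)
    activity = state.get("activity_module") or _pick_activity_module(
        counts, modules)
    seed = config["seed"]
    stage_dir = outdir / "enrich"

    sim_dir = outdir / "simulate"
    ann = state.get("annotations")
    if ann is None and (sim_dir / "tf_genes.tsv").exists():
        ann = {
            "tf_genes": pd.read_csv(sim_dir / "tf_genes.tsv",
                                    sep="\t")["gene"].tolist(),
            "gda_table": pd.read_csv(sim_dir / "gda.tsv", sep="\t"),
            "lr_table": pd.read_csv(sim_dir / "lr_pairs.tsv", sep="\t"),
        }
    if ann is None:
        raise PipelineError("no annotation tables available")

    backgrounds = state.get("backgrounds")
    if backgrounds is None:
        bg_sets = read_gene_sets(outdir / "discover" / "backgrounds.gmt")
        backgrounds = {gs.name.replace("background_", ""): gs.genes
                       for gs in bg_sets}
    background = GeneSet(
        "background",
        sorted(set().union(*backgrounds.values()) | activity.as_set()),
    )
    tf = fisher_enrichment(activity,
                           GeneSet("TF", ann["tf_genes"]), background)
    write_json({"odds_ratio": tf.odds_ratio, "p": tf.p_value,
                "table": list(tf.table)}, stage_dir / "tf_enrichment.json")

    terms = [GeneSet(term, grp["gene"].astype(str).unique().tolist())
             for term, grp in ann["gda_table"].groupby("disease")]
    if terms:
        ora(activity, terms, background).to_csv(stage_dir / "ora.tsv",
                                                sep="\t", index=False)

    universe = GeneSet("universe", list(counts.gene_ids))
    gda = gda_permutation(activity, ann["gda_table"], universe,
                          n_perm=config.get("enrichstats", {}).get(
                              "n_perm", 1000),
                          seed=seed + 30)
    write_json({"observed_fraction": gda.observed_fraction,
                "p": gda.p_value, "n_perm": gda.n_perm},
               stage_dir / "gda_permutation.json")
    state["annotations"] = ann


def _stage_interact(config: dict, outdir: Path, state: dict) -> None:
    counts = _get_counts(config, outdir, state)
    stage_dir = outdir / "interact"
    sim_dir = outdir / "simulate"
    bulk = state.get("bulk")
    if bulk is None:
        bulk = pd.read_csv(sim_dir / "bulk.tsv", sep="\t", index_col=0)
    phenotype = state.get("phenotype")
    if phenotype is None:
        phenotype = pd.read_csv(sim_dir / "phenotype.tsv", sep="\t",
                                index_col=0)
    ann = state.get("annotations")
    lr_table = (ann or {}).get("lr_table")
    if lr_table is None:
        lr_path = (config.get("input", {}).get("interaction_table")
                   or sim_dir / "lr_pairs.tsv")
        lr_table = pd.read_csv(lr_path, sep="\t")
    cfg = LRConfig(**config.get("interactions", {}))
    pairs = pair_ligand_receptor(bulk, phenotype["group"], counts,
                                 lr_table, cfg)
    pairs.to_csv(stage_dir / "lr_pairs_ranked.tsv", sep="\t", index=False)


def _stage_classify(config: dict, outdir: Path, state: dict) -> None:
    counts = _get_counts(config, outdir, state)
    modules = _load_modules(outdir, state)
    activity = state.get("activity_module") or _pick_activity_module(
        counts, modules)
    stage_dir = outdir / "classify"
    sim_dir = outdir / "simulate"
    bulk = state.get("bulk")
    if bulk is None:
        bulk = pd.read_csv(sim_dir / "bulk.tsv", sep="\t", index_col=0)
    phenotype = state.get("phenotype")
    if phenotype is None:
        phenotype = pd.read_csv(sim_dir / "phenotype.tsv", sep="\t",
                                index_col=0)
    plan = CVPlan(**{**config.get("classify", {}), "seed": config["seed"] + 40})
    control = cv2_select(counts, len(activity))
    labels = phenotype["group"].map(
        lambda g: "disease" if g == "rejection" else "healthy")
    report = compare_feature_sets(
        bulk.T, labels, {"activity_module": activity, "cv2_control": control},
        plan, group="bulk")
    report.to_csv(stage_dir / "classification.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "discover": _stage_discover,
    "consensus": _stage_consensus,
    "score": _stage_score,
    "validate": _stage_validate,
    "enrich": _stage_enrich,
    "interact": _stage_interact,
    "classify": _stage_classify,
}
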