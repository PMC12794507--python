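import numpy as np
import pandas as pd
import pytest
import scipy.stats

from crossmod import BulkConfig, CohortConfig, generate_annotations, generate_bulk, generate_cohort
from crossmod.synthgen import ConfigError


class TestCohortGenerator:
    def test_shape_bookkeeping(self, small_cohort):
        cfg = CohortConfig(n_genes=500, n_cells_per_type_per_donor=15,
                           n_module_genes=30, n_identity_genes=25, seed=11)
        expected_cells = (cfg.n_batches * len(cfg.conditions)
                          * cfg.n_donors_per_condition * len(cfg.timepoints)
                          * cfg.n_celltypes * cfg.n_cells_per_type_per_donor)
        cm = small_cohort.counts
        assert cm.n_genes == cfg.n_genes
        assert cm.n_cells == expected_cells
        assert len(cm.cell_meta) == expected_cells
        assert set(cm.cell_meta["batch"]) == {"B0", "B1", "B2"}

    def test_seeded_determinism(self):
        cfg = CohortConfig(n_genes=300, n_cells_per_type_per_donor=5,
                           n_identity_genes=20, n_module_genes=30, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        np.testing.assert_array_equal(a.counts.dense(), b.counts.dense())
        pd.testing.assert_series_equal(a.truth["cell_activity"],
                                       b.truth["cell_activity"])

    def test_counts_are_nonnegative_integers(self, small_cohort):
        X = small_cohort.counts.dense()
        assert X.min() >= 0
        np.testing.assert_array_equal(X, np.round(X))

    def test_truth_sets_subset_of_gene_universe(self, small_cohort):
        universe = set(small_cohort.counts.gene_ids)
        truth = small_cohort.truth
        assert set(truth["module_genes"]) <= universe
        for genes in truth["identity_gene_sets"].values():
            assert set(genes) <= universe
        for genes in truth["module_genes_by_batch"].values():
            assert set(genes) <= universe

    def test_trend_effect_orders_truth_activity(self):
        """With a declining rejection trend the emitted truth activity drops
        from T0 to T1 in rejection donors and stays flat in stable donors."""
        cfg = CohortConfig(n_genes=150, n_cells_per_type_per_donor=30,
                           n_module_genes=20, n_identity_genes=10,
                           trend_effect=(1.0, 0.6, 0.6), seed=5)
        cohort = generate_cohort(cfg)
        meta = cohort.counts.cell_meta
        act = cohort.truth["cell_activity"]
        means = act.groupby([meta["condition"], meta["timepoint"]]).mean()
        assert means["rejection"]["T1"] < means["rejection"]["T0"]
        # stable donors: multiplier 1.0 at every timepoint
        stable = means["stable"]
        assert abs(stable["T1"] - stable["T0"]) < 0.25 * stable["T0"]

    def test_config_invariants_name_the_field(self):
        with pytest.raises(ConfigError, match="trend_effect"):
            CohortConfig(trend_effect=(1.0, 0.5)).validate()
        with pytest.raises(ConfigError, match="n_module_genes"):
            CohortConfig(n_genes=50, n_module_genes=50).validate()
        with pytest.raises(ConfigError, match="n_genes"):
            CohortConfig(n_genes=150).validate()  # programs do not fit

    def test_batch_overlap_plants_core_plus_extras(self):
        cfg = CohortConfig(n_genes=600, n_module_genes=40,
                           module_batch_overlap=0.8,
                           n_cells_per_type_per_donor=2, seed=1)
        cohort = generate_cohort(cfg)
        core = set(cohort.truth["module_genes"])
        per_batch = cohort.truth["module_genes_by_batch"]
        for genes in per_batch.values():
            assert core <= set(genes)
            assert len(core) / len(genes) == pytest.approx(0.8, abs=0.02)
        extras = [set(g) - core for g in per_batch.values()]
        assert extras[0] & extras[1] == set()  # batch-private


class TestBulkGenerator:
    def test_null_shift_group_means_agree(self):
        bulk, phen, truth = generate_bulk(
            BulkConfig(module_shift=0.0, n_samples_per_group=100, seed=2))
        mod = bulk.loc[truth["module_genes"]]
        g = phen["group"].to_numpy()
        diff = (mod.loc[:, g == "rejection"].mean(axis=1)
                - mod.loc[:, g == "stable"].mean(axis=1))
        assert abs(diff.mean()) < 0.1

    def test_shift_detected_by_ks_on_mean_z(self):
        from crossmod import bulk_module_score, ks_compare
        from crossmod.io_core import GeneSet
        bulk, phen, truth = generate_bulk(
            BulkConfig(module_shift=1.0, n_samples_per_group=50, seed=3))
        score = bulk_module_score(bulk, GeneSet("m", truth["module_genes"]))
        g = phen["group"]
        res = ks_compare(score[g == "stable"], score[g == "rejection"])
        assert res.p_value < 0.05

    def test_ligand_tracks_latent_module_score(self):
        bulk, phen, truth = generate_bulk(
            BulkConfig(noise_sigma=0.3, n_samples_per_group=50, seed=4))
        r = np.corrcoef(bulk.loc[truth["ligand_gene"]],
                        truth["sample_score"])[0, 1]
        assert r > 0.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError, match="n_samples_per_group"):
            generate_bulk(BulkConfig(n_samples_per_group=3))

    def test_seeded_determinism(self):
        a, _, _ = generate_bulk(BulkConfig(seed=9))
        b, _, _ = generate_bulk(BulkConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestAnnotations:
    def test_null_tf_enrichment_or_near_one(self):
        """Without a planted enrichment the module's odds ratio for the TF
        annotation fluctuates around 1."""
        from crossmod import fisher_enrichment
        from crossmod.io_core import GeneSet
        genes = [f"G{i:05d}" for i in range(2000)]
        module = GeneSet("m", genes[:61])
        ors = []
        for seed in range(30):
            ann = generate_annotations(2000, tf_fraction=0.1, seed=seed)
            res = fisher_enrichment(module, GeneSet("tf", ann["tf_genes"]),
                                    GeneSet("bg", genes))
            ors.append(res.odds_ratio)
        assert 0.7 < np.median(ors) < 1.4

    def test_planted_odds_ratio_realized(self):
        from crossmod import fisher_enrichment
        from crossmod.io_core import GeneSet
        genes = [f"G{i:05d}" for i in range(2000)]
        module = genes[:61]
        ann = generate_annotations(2000, tf_fraction=0.1, seed=0,
                                   module_genes=module, tf_odds_ratio=5.0)
        res = fisher_enrichment(GeneSet("m", module),
                                GeneSet("tf", ann["tf_genes"]),
                                GeneSet("bg", genes))
        assert 3.0 <= res.odds_ratio <= 8.0

    def test_lr_table_bookkeeping(self):
        ann = generate_annotations(500, n_lr_pairs=20, seed=1)
        assert len(ann["lr_table"]) == 20
        assert set(ann["lr_table"]["category"]) <= {"cytokine", "other"}

    def test_infeasible_enrichment_is_error(self):
        genes = [f"G{i:05d}" for i in range(100)]
        with pytest.raises(ConfigError, match="infeasible"):
            generate_annotations(100, tf_fraction=0.9, seed=0,
                                 module_genes=genes[:5], tf_odds_ratio=100.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError, match="fraction"):
            generate_annotations(100, tf_fraction=1.5)
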