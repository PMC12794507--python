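import numpy as np
import pandas as pd
import pytest
import scipy.stats

from crossmod import (CountMatrix, GeneSet, PermutationConfig,
                      correlation_null_test, gradient_gene_scan, ks_compare,
                      permutation_robustness, stratify_by_module,
                      trend_regression)
from crossmod.synthgen import BulkConfig, generate_bulk
from crossmod.scoring import bulk_module_score


def _matrix(values, cell_types=None):
    values = np.asarray(values, dtype=float)
    cells = [f"c{i}" for i in range(values.shape[1])]
    meta = None
    if cell_types is not None:
        meta = pd.DataFrame({"cell_type": cell_types},
                            index=pd.Index(cells, name="cell_id"))
    return CountMatrix(values, [f"g{i}" for i in range(values.shape[0])],
                       cells, meta)


class TestCorrelationNull:
    def test_duplicated_genes_give_perfect_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5.0, 40).astype(float)
        X = rng.poisson(5.0, (30, 40)).astype(float)
        X[0] = base
        X[1] = base
        X[2] = base
        cm = _matrix(X, ["T"] * 40)
        res = correlation_null_test(cm, GeneSet("dup", ["g0", "g1", "g2"]),
                                    n_random=99, seed=1, normalize=False)
        assert res.observed["T"] == pytest.approx(1.0)
        assert res.p_value["T"] == pytest.approx(1 / 100)

    def test_independent_genes_center_at_zero(self, null_cohort):
        counts = null_cohort.counts
        sig = GeneSet("rand", counts.gene_ids[:30])
        res = correlation_null_test(counts, sig, n_random=100, seed=2)
        for ct in res.observed.index:
            assert abs(res.observed[ct]) < 0.05
            assert round(float(res.null_mean[ct]), 2) == 0.0

    def test_too_small_gene_set_rejected(self, null_cohort):
        with pytest.raises(ValueError, match=">= 2"):
            correlation_null_test(null_cohort.counts,
                                  GeneSet("one", ["G00000"]), n_random=10)


class TestTrendRegression:
    @staticmethod
    def _meta(celltype, condition, timepoints):
        idx = pd.Index([f"c{i}" for i in range(len(timepoints))],
                       name="cell_id")
        return pd.DataFrame({"cell_type": celltype, "condition": condition,
                             "timepoint": timepoints}, index=idx)

    def test_perfect_line_has_unit_slope(self):
        meta = self._meta("T", "stable", ["T0", "T1", "T2"])
        scores = pd.Series([0.0, 1.0, 2.0], index=meta.index)
        res = trend_regression(scores, meta)
        assert res.loc[0, "beta"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_scores_have_zero_slope(self):
        meta = self._meta("T", "stable", ["T0", "T1", "T2", "T0", "T2"])
        scores = pd.Series(0.4, index=meta.index)
        res = trend_regression(scores, meta)
        assert res.loc[0, "beta"] == pytest.approx(0.0, abs=1e-12)

    def test_slope_equals_closed_form_covariance_ratio(self):
        rng = np.random.default_rng(3)
        tps = rng.choice(["T0", "T1", "T2"], 200)
        meta = self._meta("T", "stable", tps)
        scores = pd.Series(rng.normal(0, 1, 200), index=meta.index)
        res = trend_regression(scores, meta)
        tau = pd.Series(tps).map({"T0": 0.0, "T1": 1.0, "T2": 2.0}).to_numpy()
        y = scores.to_numpy()
        beta_closed = np.cov(tau, y, ddof=1)[0, 1] / np.var(tau, ddof=1)
        assert res.loc[0, "beta"] == pytest.approx(beta_closed, abs=1e-10)

    def test_declining_rejection_trend_recovered_from_truth(self):
        """Regressing the generator's own truth activity on time finds the
        planted negative slope in rejection and none in stable donors."""
        from crossmod import CohortConfig, generate_cohort
        cohort = generate_cohort(CohortConfig(
            n_genes=120, n_celltypes=2, n_identity_genes=10,
            n_module_genes=20, n_cells_per_type_per_donor=170,
            trend_effect=(1.0, 0.6, 0.6), seed=21,
        ))
        meta = cohort.counts.cell_meta
        act = cohort.truth["cell_activity"]
        res = trend_regression(act, meta).set_index(["condition", "cell_type"])
        rej = res.loc["rejection"]
        sta = res.loc["stable"]
        assert (rej["beta"] < 0).all()
        assert (rej["p"] < 0.05).all()
        assert (sta["beta"].abs() < rej["beta"].abs().min()).all()

    def test_single_timepoint_omitted(self):
        meta = self._meta("T", "stable", ["T0", "T0", "T0"])
        res = trend_regression(pd.Series([1.0, 2.0, 3.0], index=meta.index),
                               meta)
        assert res.empty

    def test_reverse_flag_preserves_sign(self):
        meta = self._meta("T", "stable", ["T0", "T1", "T2", "T1"])
        scores = pd.Series([0.1, 0.5, 0.9, 0.4], index=meta.index)
        fwd = trend_regression(scores, meta)
        rev = trend_regression(scores, meta, reverse=True)
        assert np.sign(fwd.loc[0, "beta"]) == np.sign(rev.loc[0, "beta"])


def brute_force_bh(p, alpha):
    """Textbook step-up BH: reject the largest k with p_(k) <= k/m * alpha."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if len(below):
        reject[order[: below.max() + 1]] = True
    return reject


class TestPermutationRobustness:
    def test_degenerate_equal_groups_nothing_significant(self):
        """Constant identical score vectors: every subsample is all ties, so
        every raw p is 1 and nothing survives BH."""
        x = pd.Series(np.full(300, 0.5))
        cfg = PermutationConfig(n_cells=50, n_perm=100, seed=0)
        res = permutation_robustness(x, x.copy(), cfg)
        assert res.proportion_significant == 0.0
        assert (res.p_raw == 1.0).all()

    def test_same_distribution_rarely_significant(self):
        """Independent draws from one distribution: BH across repetitions
        keeps the significant proportion near zero."""
        x = pd.Series(np.linspace(0, 1, 300))
        cfg = PermutationConfig(n_cells=50, n_perm=200, seed=0)
        res = permutation_robustness(x, x.copy(), cfg)
        assert res.proportion_significant <= 0.01

    def test_group_smaller_than_subsample_is_error(self):
        cfg = PermutationConfig(n_cells=100, n_perm=10)
        with pytest.raises(ValueError, match="group B has 50"):
            permutation_robustness(pd.Series(np.ones(200)),
                                   pd.Series(np.ones(50)), cfg)

    def test_proportion_matches_brute_force_bh(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.normal(0.0, 1.0, 500))
        b = pd.Series(rng.normal(0.25, 1.0, 500))
        cfg = PermutationConfig(n_cells=100, n_perm=200, seed=5)
        res = permutation_robustness(a, b, cfg)
        reject = brute_force_bh(res.p_raw, cfg.alpha)
        assert res.proportion_significant == pytest.approx(reject.mean())
        assert (res.p_adjusted >= res.p_raw - 1e-15).all()

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(6)
        a = pd.Series(rng.normal(0, 1, 400))
        b = pd.Series(rng.normal(0.3, 1, 400))
        res = permutation_robustness(
            a, b, PermutationConfig(n_cells=80, n_perm=150, seed=7))
        order = np.argsort(res.p_raw)
        assert np.all(np.diff(res.p_adjusted[order]) >= -1e-15)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 1000)
        props = []
        for shift in (0.1, 0.4, 1.0):
            a = pd.Series(base)
            b = pd.Series(rng.normal(shift, 1, 1000))
            cfg = PermutationConfig(n_cells=100, n_perm=150, seed=9)
            props.append(permutation_robustness(a, b, cfg)
                         .proportion_significant)
        assert props[0] <= props[1] <= props[2]
        assert props[2] > 0.9


def ecdf_enumeration_D(a, b):
    """O(n·m) oracle: max |ECDF_a − ECDF_b| evaluated at every data point."""
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        d = abs((a <= x).mean() - (b <= x).mean())
        best = max(best, d)
    return best


class TestKSCompare:
    def test_identical_samples_have_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ks_compare(x, x).D == 0.0

    def test_fully_separated_samples_have_unit_distance(self):
        assert ks_compare(np.array([1.0, 2.0]), np.array([5.0, 6.0])).D == 1.0

    def test_interleaved_toy_value(self):
        res = ks_compare(np.array([1.0, 3.0]), np.array([2.0, 4.0]))
        assert res.D == pytest.approx(0.5)

    def test_matches_ecdf_enumeration_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 12))
            assert ks_compare(a, b).D == pytest.approx(
                ecdf_enumeration_D(a, b), abs=1e-12)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([]), np.array([1.0]))


class TestStratifyByModule:
    def test_eight_equally_spaced_scores_split_2_4_2(self):
        scores = pd.Series(np.arange(8.0), index=[f"s{i}" for i in range(8)])
        target = pd.Series(np.ones(8), index=scores.index)
        res = stratify_by_module(scores, target)
        assert res["sizes"] == {"low": 2, "mid": 4, "high": 2}

    def test_ligand_higher_in_high_module_stratum(self):
        bulk, phen, truth = generate_bulk(
            BulkConfig(n_samples_per_group=50, ligand_beta=1.0,
                       noise_sigma=0.3, seed=12))
        score = bulk_module_score(bulk, GeneSet("m", truth["module_genes"]))
        res = stratify_by_module(score, bulk.loc[truth["ligand_gene"]])
        comp = res["comparisons"]["low_vs_high"]
        assert comp["mean_high"] > comp["mean_low"]
        assert comp["p"] < 0.05

    def test_too_few_samples_is_error(self):
        s = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 4"):
            stratify_by_module(s, s)


class TestGradientGeneScan:
    def _scan_input(self, gene_means, n_cells=600, seed=0):
        """gene_means: per condition list of per-gene expected values."""
        rng = np.random.default_rng(seed)
        blocks, codes = [], []
        for code, means in enumerate(gene_means):
            blocks.append(rng.poisson(np.asarray(means)[:, None],
                                      (len(means), n_cells)).astype(float))
            codes += [code] * n_cells
        X = np.hstack(blocks)
        cm = _matrix(X)
        return cm, pd.Series(codes, index=cm.cell_ids, dtype=float)

    def test_graded_gene_detected(self):
        cm, codes = self._scan_input([[1.0], [2.0], [3.0]])
        res = gradient_gene_scan(cm, codes, n_groups=10, min_cells=50, seed=1)
        assert res.loc["g0", "slope"] > 0
        assert res.loc["g0", "p"] < 0.05
        assert res.loc["g0", "direction"] == "up"

    def test_infeasible_grouping_reports_achievable(self):
        cm, codes = self._scan_input([[1.0], [1.0], [1.0]], n_cells=400)
        with pytest.raises(ValueError, match="at most 8 groups"):
            gradient_gene_scan(cm, codes, n_groups=10, min_cells=50)

    def test_flat_genes_reject_at_nominal_rate(self):
        means = [[5.0] * 300] * 3
        cm, codes = self._scan_input(means, n_cells=550, seed=2)
        res = gradient_gene_scan(cm, codes, n_groups=10, min_cells=50, seed=3)
        rate = res["significant"].mean()
        assert rate == pytest.approx(0.05, abs=0.035)
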