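import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from crossmod import fisher_enrichment, gda_permutation, ora
from crossmod.io_core import GeneSet


def _sets_for_table(a, b, c, d):
    """Construct module/category/background gene sets realizing the
    2x2 table (a, b; c, d)."""
    genes = [f"g{i}" for i in range(a + b + c + d)]
    module = genes[: a + b]
    category = genes[:a] + genes[a + b: a + b + c]
    return (GeneSet("mod", module), GeneSet("cat", category),
            GeneSet("bg", genes))


def enumeration_fisher_p(a, b, c, d):
    """Brute-force two-sided Fisher p: sum the probabilities of all tables
    with the same margins whose probability does not exceed the observed."""
    n1, n2 = a + b, c + d
    k = a + c
    N = n1 + n2
    def prob(x):
        return (math.comb(n1, x) * math.comb(n2, k - x)) / math.comb(N, k)
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


class TestFisherEnrichment:
    def test_cross_product_odds_ratio(self):
        res = fisher_enrichment(*_sets_for_table(20, 10, 10, 20))
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.table == (20, 10, 10, 20)

    def test_balanced_table_p_is_one(self):
        res = fisher_enrichment(*_sets_for_table(5, 5, 5, 5))
        assert res.p_value == pytest.approx(1.0)

    def test_p_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = fisher_enrichment(*_sets_for_table(a, b, c, d))
            assert res.p_value == pytest.approx(
                enumeration_fisher_p(a, b, c, d), abs=1e-10)

    def test_zero_cell_gets_haldane_flag(self):
        res = fisher_enrichment(*_sets_for_table(5, 0, 3, 7))
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)

    def test_module_outside_background_is_error(self):
        with pytest.raises(ValueError, match="outside the background"):
            fisher_enrichment(GeneSet("m", ["x"]), GeneSet("c", ["a"]),
                              GeneSet("bg", ["a", "b"]))

    def test_random_module_is_null(self):
        """Modules drawn uniformly from the background are unenriched: OR
        hovers around 1 and p is not systematically small."""
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(500)]
        category = GeneSet("cat", genes[:100])
        bg = GeneSet("bg", genes)
        ors, ps = [], []
        for _ in range(100):
            module = GeneSet("m", list(rng.choice(genes, 50, replace=False)))
            res = fisher_enrichment(module, category, bg)
            ors.append(res.odds_ratio)
            ps.append(res.p_value)
        assert 0.8 < np.median(ors) < 1.25
        assert np.mean(ps) > 0.3


class TestOra:
    def test_closed_form_half_background_term(self):
        """Module of 10 entirely inside a term covering half the background:
        p equals the closed-form hypergeometric upper tail at k = n."""
        genes = [f"g{i}" for i in range(200)]
        module = GeneSet("m", genes[:10])
        term = GeneSet("t", genes[:100])
        out = ora(module, [term], GeneSet("bg", genes))
        want = scipy.stats.hypergeom.sf(9, 200, 100, 10)
        closed = (math.comb(100, 10) / math.comb(200, 10))
        assert out.loc[0, "p"] == pytest.approx(want, rel=1e-12)
        assert out.loc[0, "p"] == pytest.approx(closed, rel=1e-9)

    def test_disjoint_term_upper_tail_is_one(self):
        genes = [f"g{i}" for i in range(50)]
        out = ora(GeneSet("m", genes[:5]), [GeneSet("t", genes[40:])],
                  GeneSet("bg", genes))
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_stable_under_duplicated_terms(self):
        genes = [f"g{i}" for i in range(100)]
        module = GeneSet("m", genes[:10])
        term = GeneSet("t", genes[:30])
        dup = GeneSet("t_copy", genes[:30])
        out = ora(module, [term, dup], GeneSet("bg", genes))
        assert out["fdr"].nunique() == 1

    def test_p_monotone_decreasing_in_overlap(self):
        genes = [f"g{i}" for i in range(200)]
        bg = GeneSet("bg", genes)
        ps = []
        for k in (2, 5, 8):
            module = GeneSet("m", genes[:k] + genes[100:100 + 10 - k])
            term = GeneSet("t", genes[:50])
            ps.append(ora(module, [term], bg).loc[0, "p"])
        assert ps[0] > ps[1] > ps[2]

    def test_term_disjoint_from_background_skipped(self):
        genes = [f"g{i}" for i in range(20)]
        with pytest.warns(UserWarning, match="disjoint"):
            out = ora(GeneSet("m", genes[:3]),
                      [GeneSet("t", ["zz1", "zz2"]),
                       GeneSet("u", genes[:10])],
                      GeneSet("bg", genes))
        assert list(out["term"]) == ["u"]


class TestGdaPermutation:
    def _table(self, genes):
        return pd.DataFrame({"gene": genes,
                             "disease": ["d0"] * len(genes)})

    def test_observed_fraction_24_of_61(self):
        genes = [f"g{i}" for i in range(2000)]
        module = GeneSet("m", genes[:61])
        table = self._table(genes[:24] + genes[500:700])
        res = gda_permutation(module, table, GeneSet("u", genes),
                              n_perm=50, seed=0)
        assert res.observed_fraction == pytest.approx(24 / 61)
        assert round(res.observed_fraction, 4) == 0.3934

    def test_fully_associated_universe_is_trivial(self):
        genes = [f"g{i}" for i in range(100)]
        res = gda_permutation(GeneSet("m", genes[:10]), self._table(genes),
                              GeneSet("u", genes), n_perm=50, seed=1)
        assert res.observed_fraction == 1.0
        assert (res.null_fractions == 1.0).all()
        assert res.p_value == pytest.approx(1.0)

    def test_strong_enrichment_hits_add_one_floor(self):
        genes = [f"g{i}" for i in range(2000)]
        module = GeneSet("m", genes[:61])
        # module fully associated, universe only 5% associated
        table = self._table(genes[:61] + genes[1000:1039])
        res = gda_permutation(module, table, GeneSet("u", genes),
                              n_perm=200, seed=2)
        assert res.p_value == pytest.approx(1 / 201)

    def test_p_never_zero(self):
        genes = [f"g{i}" for i in range(50)]
        res = gda_permutation(GeneSet("m", genes[:5]), self._table(genes[:5]),
                              GeneSet("u", genes), n_perm=20, seed=3)
        assert res.p_value >= 1 / 21
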