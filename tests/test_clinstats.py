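"""Cutoff dichotomization and the clinical-table test battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fragmeth.clinstats import (
    compare_groups,
    dichotomize,
    fisher_exact_2x2,
    mann_whitney,
    methylation_cutoff,
    pearson_chi2,
    spearman,
)

# Mutation-flag 2x2 tables (mutant/wild-type in non-hyper vs hyper patients)
# from the clinical cohort this pipeline models, with their published
# two-sided Fisher p-values.
TABLE1_FISHER = {
    "CEBPA": ((1, 61, 2, 30), 0.266),
    "IDH1/2": ((3, 59, 1, 31), 1.000),
    "DNMT3A": ((2, 60, 1, 31), 1.000),
    "U2AF1": ((1, 61, 5, 27), 0.016),
    "SRSF2": ((2, 60, 1, 31), 1.000),
    "SF3B1": ((3, 59, 3, 29), 0.406),
    "SETBP1": ((0, 62, 1, 31), 0.340),
}


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of the hypergeometric support:
    sum of P(table) over all tables with the observed margins whose
    probability is <= the observed table's."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    rv = stats.hypergeom(n, r1, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestCutoff:
    def test_zero_sd(self):
        assert methylation_cutoff([0.10, 0.10, 0.10]) == pytest.approx(0.10)

    def test_closed_form(self):
        assert methylation_cutoff([0.0, 2.0]) == pytest.approx(1 + 2 * np.sqrt(2))

    def test_population_sd_option(self):
        assert methylation_cutoff([0.0, 2.0], ddof=0) == pytest.approx(3.0)

    def test_boundary_value_is_not_hypermethylated(self):
        cutoff = methylation_cutoff([0.1, 0.1])
        assert dichotomize([cutoff, cutoff + 1e-9], cutoff).tolist() == [0, 1]

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            methylation_cutoff([0.5])

    def test_normal_controls_exceed_cutoff_at_two_sd_rate(self):
        """mean+2SD of a normal sample is exceeded by ~2.3% of values."""
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(200):
            ctrl = rng.normal(0.3, 0.08, size=500)
            cutoff = methylation_cutoff(ctrl)
            rates.append((rng.normal(0.3, 0.08, size=500) > cutoff).mean())
        assert np.mean(rates) == pytest.approx(0.0228, abs=0.01)


class TestFisher:
    @pytest.mark.parametrize("gene", TABLE1_FISHER)
    def test_reproduces_published_p_values(self, gene):
        (a, b, c, d), expected = TABLE1_FISHER[gene]
        assert round(fisher_exact_2x2(a, b, c, d), 3) == pytest.approx(expected)

    def test_setbp1_table_is_analytic(self):
        # single-count margin: p = 32/94 exactly
        assert fisher_exact_2x2(0, 62, 1, 31) == pytest.approx(32 / 94, rel=1e-9)

    def test_symmetric_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_degenerate_margin(self, caplog):
        assert fisher_exact_2x2(0, 0, 3, 5) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        # exhaustive over small tables
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            fisher_enumeration_oracle(a, b, c, d), rel=1e-7
                        ), (a, b, c, d)
        # random tables up to N = 200
        for _ in range(150):
            t = rng.multinomial(int(rng.integers(4, 201)), [0.25] * 4)
            a, b, c, d = (int(x) for x in t)
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), rel=1e-7
            )

    def test_invariance_under_row_and_column_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(d, c, b, a), rel=1e-9
            )


class TestChi2:
    def test_observed_equals_expected(self):
        stat, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        obs = rng.integers(5, 50, size=(3, 4)).astype(float)
        expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        stat, _ = pearson_chi2(obs)
        assert stat == pytest.approx(by_hand)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            pearson_chi2([[0, 0], [3, 5]])


class TestMannWhitney:
    def test_identical_samples(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_small_sample(self):
        # all C(4,2)=6 rank splits; {1,2} vs {3,4} is one extreme -> 2/6
        assert mann_whitney([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(0.5, size=6)
            exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
            ours = mann_whitney(x, y)  # n=12 without ties -> exact branch
            assert ours == pytest.approx(exact, abs=1e-12)
            approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(ours - approx) < 0.02


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman(x, [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)


class TestCompareGroups:
    def _clinical(self):
        # mutation flags laid out to reproduce the published U2AF1 table:
        # 1 mutant / 61 wild-type among non-hyper, 5 / 27 among hyper
        rows = (
            [{"hypermethylated": 0, "U2AF1": 1}] * 1
            + [{"hypermethylated": 0, "U2AF1": 0}] * 61
            + [{"hypermethylated": 1, "U2AF1": 1}] * 5
            + [{"hypermethylated": 1, "U2AF1": 0}] * 27
        )
        return pd.DataFrame(rows)

    def test_sparse_2x2_routes_to_fisher(self):
        res = compare_groups(self._clinical(), "U2AF1", "categorical")
        assert res.test == "fisher"
        assert round(res.p_value, 3) == pytest.approx(0.016)

    def test_balanced_2x2_routes_to_chi_square(self):
        rows = (
            [{"hypermethylated": 0, "sex": s} for s in [1] * 39 + [0] * 29]
            + [{"hypermethylated": 1, "sex": s} for s in [1] * 19 + [0] * 18]
        )
        res = compare_groups(pd.DataFrame(rows), "sex", "categorical")
        assert res.test == "chi-square"
        assert 0 <= res.p_value <= 1

    def test_continuous_routes_to_mann_whitney(self):
        df = pd.DataFrame(
            {"hypermethylated": [0] * 10 + [1] * 10,
             "wbc": np.r_[np.arange(10), np.arange(10) + 5].astype(float)}
        )
        res = compare_groups(df, "wbc", "continuous")
        assert res.test == "mann-whitney"

    def test_missing_values_dropped(self):
        df = self._clinical()
        df.loc[df.index[:10], "U2AF1"] = np.nan
        res = compare_groups(df, "U2AF1", "categorical")
        assert 0 <= res.p_value <= 1

    def test_unknown_or_empty_variable(self):
        df = self._clinical()
        with pytest.raises(KeyError):
            compare_groups(df, "nope", "categorical")
        df["allmiss"] = np.nan
        with pytest.raises(ValueError):
            compare_groups(df, "allmiss", "categorical")
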