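import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from tetradscreen.contingency import (
    PairedTable, TwoByTwo, clopper_pearson, dx_accuracy, fisher_exact, koopman_rr_ci,
    mcnemar, odds_ratio, or_ci_logit,
)


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by exhaustive hypergeometric enumeration
    with rational arithmetic (probability-at-most-observed rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((42, 70, 5, 41), 4.92),     # small sac x abnormal karyotype
            ((71, 41, 11, 35), 5.51),    # short embryo x abnormal karyotype
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_published_sample_ors(self, cells, expected):
        assert odds_ratio(TwoByTwo(*cells)) == pytest.approx(expected, abs=0.005)

    def test_haldane_anscombe_corrected_tetrad_or(self):
        t = TwoByTwo(9, 0, 103, 46)
        assert odds_ratio(t, correct_zero=True) == pytest.approx(9.5 * 46.5 / (0.5 * 103.5))
        assert odds_ratio(t, correct_zero=True) == pytest.approx(8.54, abs=0.005)

    def test_zero_cell_without_correction_raises(self):
        with pytest.raises(ValueError, match="zero"):
            odds_ratio(TwoByTwo(9, 0, 103, 46), correct_zero=False)

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_label_transposition_invariance(self, cells):
        a, b, c, d = cells
        orig = odds_ratio(TwoByTwo(a, b, c, d), correct_zero=False)
        transposed = odds_ratio(TwoByTwo(a, c, b, d), correct_zero=False)
        swapped = odds_ratio(TwoByTwo(c, d, a, b), correct_zero=False)
        assert transposed == pytest.approx(orig)
        assert swapped == pytest.approx(1 / orig)


class TestWoolfInterval:
    @pytest.mark.parametrize(
        "cells, lo, hi",
        [
            ((61, 51, 16, 30), 1.10, 4.57),     # bradycardia row
            ((42, 70, 5, 41), 1.80, 13.43),     # small sac row
            ((71, 41, 11, 35), 2.53, 12.01),    # short embryo row
        ],
    )
    def test_published_cis(self, cells, lo, hi):
        got = or_ci_logit(TwoByTwo(*cells))
        assert got[0] == pytest.approx(lo, abs=0.005)
        assert got[1] == pytest.approx(hi, abs=0.005)

    def test_corrected_tetrad_ci(self):
        got = or_ci_logit(TwoByTwo(9, 0, 103, 46), correct_zero=True)
        assert got[0] == pytest.approx(0.49, abs=0.005)
        assert got[1] == pytest.approx(149.77, abs=0.005)

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_interval_contains_point_estimate(self, cells):
        t = TwoByTwo(*cells)
        lo, hi = or_ci_logit(t)
        assert lo <= odds_ratio(t) <= hi

    def test_interval_narrows_at_lower_level(self):
        t = TwoByTwo(20, 10, 10, 20)
        lo95, hi95 = or_ci_logit(t, level=0.95)
        lo80, hi80 = or_ci_logit(t, level=0.80)
        assert lo95 < lo80 < hi80 < hi95


class TestKoopmanRiskRatioCI:
    def test_contains_sample_risk_ratio(self):
        t = TwoByTwo(30, 10, 15, 25)
        rr = (30 / 40) / (15 / 40)
        lo, hi = koopman_rr_ci(t)
        assert lo < rr < hi

    def test_handles_zero_cells(self):
        lo, hi = koopman_rr_ci(TwoByTwo(9, 0, 103, 46))
        assert 0 <= lo < hi

    def test_close_to_log_delta_interval_at_large_n(self):
        t = TwoByTwo(300, 700, 150, 850)
        p1, p0 = 0.3, 0.15
        se = math.sqrt((1 - p1) / (1000 * p1) + (1 - p0) / (1000 * p0))
        lo_d, hi_d = 2.0 * math.exp(-1.96 * se), 2.0 * math.exp(1.96 * se)
        lo, hi = koopman_rr_ci(t)
        assert lo == pytest.approx(lo_d, rel=0.02)
        assert hi == pytest.approx(hi_d, rel=0.02)


class TestFisherExact:
    def test_published_tetrad_p(self):
        assert fisher_exact(TwoByTwo(9, 0, 103, 46)) == pytest.approx(0.06, abs=0.005)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact(TwoByTwo(3, 0, 5, 0)) == 1.0
        assert fisher_exact(TwoByTwo(0, 0, 5, 3)) == 1.0

    def test_small_table_matches_hand_enumeration(self):
        # margins (4, 4) x (4, 4): 5 admissible tables
        assert fisher_exact(TwoByTwo(3, 1, 1, 3)) == pytest.approx(fisher_oracle(3, 1, 1, 3))
        assert fisher_oracle(3, 1, 1, 3) == pytest.approx((1 + 16 + 16 + 1) / 70)

    def test_agrees_with_enumeration_oracle_small_tables(self):
        """Every 2x2 table with total n <= 15."""
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = fisher_exact(TwoByTwo(a, b, c, d))
                        assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)


class TestMcNemar:
    def test_chi_square_branch_at_10_discordant(self):
        stat, p, method = mcnemar(PairedTable(5, 10, 10, 5))
        assert method == "chi2_cc"
        assert stat == pytest.approx((abs(10 - 10) - 1) ** 2 / 20)  # 0.05
        assert p == pytest.approx(0.823, abs=0.001)

    def test_exact_binomial_branch_below_10(self):
        # 9 discordant pairs: exact two-sided p = 2 * P(X <= 2 | 9, 0.5)
        stat, p, method = mcnemar(PairedTable(0, 7, 2, 0))
        assert method == "exact_binomial" and stat is None
        assert p == pytest.approx(2 * (1 + 9 + 36) / 512, abs=1e-12)

    def test_ten_discordant_pairs_use_chi_square(self):
        # the continuity-corrected chi-square applies from 10 discordant
        # pairs upward (inclusive)
        stat, p, method = mcnemar(PairedTable(0, 8, 2, 0))
        assert method == "chi2_cc"
        assert stat == pytest.approx((abs(8 - 2) - 1) ** 2 / 10)

    def test_no_discordant_pairs_degenerate(self):
        stat, p, method = mcnemar(PairedTable(4, 0, 0, 6))
        assert (stat, p, method) == (None, 1.0, "degenerate")

    @pytest.mark.parametrize("m, t", [(1, 3), (0, 5), (4, 4), (7, 2)])
    def test_exact_branch_matches_statsmodels(self, m, t):
        _, p, method = mcnemar(PairedTable(2, m, t, 3))
        assert method == "exact_binomial"
        sm = sm_mcnemar([[2, m], [t, 3]], exact=True)
        assert p == pytest.approx(float(sm.pvalue), abs=1e-10)


class TestClopperPearson:
    def test_published_full_specificity_bound(self):
        lo, hi = clopper_pearson(46, 46)
        assert lo == pytest.approx(0.9229, abs=0.0001)
        assert hi == 1.0

    def test_published_full_ppv_bound(self):
        lo, hi = clopper_pearson(9, 9)
        assert lo == pytest.approx(0.6637, abs=0.0001)

    def test_zero_successes_lower_bound_exactly_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_matches_beta_quantile_arithmetic(self):
        from scipy.stats import beta

        for k, n in [(3, 20), (15, 40), (1, 7)]:
            lo, hi = clopper_pearson(k, n)
            assert lo == pytest.approx(beta.ppf(0.025, k, n - k + 1), abs=1e-12)
            assert hi == pytest.approx(beta.ppf(0.975, k + 1, n - k), abs=1e-12)

    def test_coverage_at_nominal_level(self):
        """Exact intervals cover the true proportion in at least ~95% of
        seeded binomial replicates."""
        rng = np.random.default_rng(3)
        p_true, n = 0.3, 50
        draws = rng.binomial(n, p_true, size=2000)
        covered = sum(1 for k in draws if clopper_pearson(int(k), n)[0] <= p_true <= clopper_pearson(int(k), n)[1])
        assert covered / 2000 >= 0.94


class TestDxAccuracy:
    def test_published_tetrad_metrics(self):
        acc = dx_accuracy(tp=9, fp=0, fn=103, tn=46)
        assert acc.ppv.estimate == 1.0
        assert acc.ppv.lo == pytest.approx(0.6637, abs=0.0001)
        assert acc.specificity.estimate == 1.0
        assert acc.specificity.lo == pytest.approx(0.9229, abs=0.0001)

    def test_perfect_classifier(self):
        acc = dx_accuracy(5, 0, 0, 5)
        for m in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv, acc.accuracy):
            assert m.estimate == 1.0

    def test_uninformative_classifier(self):
        acc = dx_accuracy(1, 1, 1, 1)
        for m in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv, acc.accuracy):
            assert m.estimate == 0.5

    def test_empty_denominator_reported_as_none(self):
        acc = dx_accuracy(tp=0, fp=0, fn=3, tn=5)
        assert acc.ppv is None
        assert acc.specificity.estimate == 1.0

    def test_point_estimates_inside_cis(self):
        acc = dx_accuracy(12, 4, 7, 30)
        for m in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv, acc.accuracy):
            assert m.lo <= m.estimate <= m.hi


def test_invalid_tables_rejected():
    with pytest.raises(ValueError):
        TwoByTwo(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        TwoByTwo(0, 0, 0, 0)
    with pytest.raises(ValueError):
        PairedTable(-1, 0, 0, 0)
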