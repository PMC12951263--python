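import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from tetradscreen.descriptive import (
    categorical_test, fisher_exact_rxc, mann_whitney_u, median_iqr, shapiro_wilk,
    summarize_categorical, summarize_continuous,
)


class TestMedianIqr:
    def test_odd_sample(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_single_value(self):
        assert median_iqr([7.0]) == (7, 7, 7)

    def test_even_sample_linear_interpolation(self):
        assert median_iqr([1, 2, 3, 4]) == (2.5, 1.75, 3.25)

    def test_missing_excluded(self):
        assert median_iqr([1, np.nan, 2, 3, np.nan, 4, 5]) == (3, 2, 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([np.nan])


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_exact_matches_rank_enumeration(self):
        """Exact p agrees with enumeration of all rank arrangements."""
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        u_obs, p = mann_whitney_u(x, y)
        n, m = len(x), len(y)
        us = []
        for combo in itertools.combinations(range(n + m), n):
            ranks = set(combo)
            u = sum(1 for i in ranks for j in range(n + m) if j not in ranks and i > j)
            us.append(u)
        extreme = sum(1 for u in us if min(u, n * m - u) <= min(u_obs, n * m - u_obs))
        assert p == pytest.approx(extreme / len(us))

    def test_shift_alternative_has_power(self):
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(200):
            x = rng.normal(0, 1, 30)
            y = rng.normal(1.0, 1, 30)
            if mann_whitney_u(x, y)[1] < 0.05:
                rejections += 1
        assert rejections / 200 > 0.5


def rxc_oracle(table):
    """Brute-force r x c Fisher oracle: iterate every cell assignment with
    the observed margins, rational hypergeometric probabilities."""
    table = np.asarray(table, int)
    r, c = table.shape
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    n = table.sum()

    from math import factorial

    def prob(t):
        # multiple hypergeometric: prod(r_i!) prod(c_j!) / (n! prod(a_ij!))
        p = Fraction(1)
        for rt in row_tot:
            p *= factorial(int(rt))
        for ct in col_tot:
            p *= factorial(int(ct))
        q = Fraction(factorial(int(n)))
        for v in t.ravel():
            q *= factorial(int(v))
        return p / q

    p_obs = prob(table)
    total = Fraction(0)
    ranges = [range(min(int(row_tot[i]), int(col_tot[j])) + 1)
              for i in range(r - 1) for j in range(c - 1)]
    for cells in itertools.product(*ranges):
        t = np.zeros((r, c), int)
        for k, (i, j) in enumerate(itertools.product(range(r - 1), range(c - 1))):
            t[i, j] = cells[k]
        for i in range(r - 1):
            t[i, c - 1] = row_tot[i] - t[i, :c - 1].sum()
        for j in range(c):
            t[r - 1, j] = col_tot[j] - t[:r - 1, j].sum()
        if (t >= 0).all():
            if prob(t) <= p_obs:
                total += prob(t)
    return float(total)


class TestCategoricalTest:
    def test_identical_rows_give_p_one(self):
        name, p = categorical_test([[10, 10], [10, 10]])
        assert name == "chi_square"
        assert p == pytest.approx(1.0)

    def test_low_expected_count_routes_to_fisher(self):
        name, _ = categorical_test([[2, 8], [3, 7]])
        assert name == "fisher_exact"

    def test_chi_square_statistic_uncorrected(self):
        name, p = categorical_test([[20, 10], [10, 20]])
        assert name == "chi_square"
        # Pearson statistic 20/3 = 6.67 on 1 df, no continuity correction
        assert p == pytest.approx(float(stats.chi2.sf(20 / 3, 1)), abs=1e-12)

    def test_degenerate_margin(self):
        name, p = categorical_test([[0, 0], [5, 3]])
        assert (name, p) == ("degenerate", 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[-1, 2], [3, 4]])


class TestFisherRxC:
    def test_2x2_delegates_to_exact_2x2(self):
        table = [[2, 8], [3, 7]]
        assert fisher_exact_rxc(np.array(table)) == pytest.approx(
            float(stats.fisher_exact(table)[1]))

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1, 2], [1, 4, 1]],
            [[2, 0, 3], [1, 2, 0], [0, 3, 1]],
            [[5, 1], [2, 3], [1, 4]],
        ],
    )
    def test_enumeration_matches_brute_force_oracle(self, table):
        got = fisher_exact_rxc(np.array(table))
        assert got == pytest.approx(rxc_oracle(table), abs=1e-10)

    def test_monte_carlo_branch_close_to_enumeration(self):
        # inflate a small table beyond the enumeration limit and compare
        # the seeded Monte-Carlo p with the chi-square asymptote
        table = np.array([[40, 80, 30], [60, 70, 25]])
        p_mc = fisher_exact_rxc(table, seed=1)
        p_chi = float(stats.chi2_contingency(table, correction=False).pvalue)
        assert p_mc == pytest.approx(p_chi, abs=0.05)

    def test_monte_carlo_deterministic_under_seed(self):
        table = np.array([[40, 80, 30], [60, 70, 25]])
        assert fisher_exact_rxc(table, seed=5) == fisher_exact_rxc(table, seed=5)


class TestShapiroWilk:
    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_guarded(self):
        w, p = shapiro_wilk([3.0] * 10)
        assert w == 0.0 and p == 0.0

    def test_detects_lognormal_skew(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(50):
            sample = np.exp(rng.normal(0, 1, 100))
            if shapiro_wilk(sample)[1] < 0.05:
                hits += 1
        assert hits / 50 > 0.9

    def test_near_uniform_p_under_normality(self):
        rng = np.random.default_rng(12)
        ps = [shapiro_wilk(rng.normal(size=80))[1] for _ in range(200)]
        # uniformity: roughly 5% below 0.05 and median near 0.5
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac <= 0.12
        assert 0.3 < np.median(ps) < 0.7


class TestSummaries:
    def test_continuous_summary_format_and_p(self):
        s = summarize_continuous("age", [35, 33, 38, 34], [38, 41, 34, 40])
        assert s.test == "mann_whitney_u"
        assert "(" in s.normal and 0 <= s.p <= 1

    def test_categorical_percentages_use_group_denominators(self):
        rows = summarize_categorical("mode", [38, 8], [93, 19], ["spontaneous", "ART"])
        assert rows[0].normal == f"38 ({100 * 38 / 46:.1f})"
        assert rows[0].abnormal == f"93 ({100 * 93 / 112:.1f})"
        assert rows[0].p == rows[1].p  # one shared test per variable
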