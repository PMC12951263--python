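"""Group-comparison statistics for the baseline and sonographic tables.

Continuous variables are summarised as median (IQR) and compared with the
Mann-Whitney U-test; categorical variables as n (%) and compared with the
chi-square test when every expected cell count is at least 5 and Fisher's
exact test otherwise.  Shapiro-Wilk normality testing backs the choice of
nonparametric reporting.

scipy provides the chi-square, Mann-Whitney, Shapiro-Wilk and 2x2 Fisher
machinery; the r x c Fisher exact test (which scipy lacks) is computed
here by full enumeration of tables with the observed margins for totals
up to 200 and by seeded Monte-Carlo sampling beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .contingency import TwoByTwo, fisher_exact

__all__ = [
    "GroupSummary",
    "median_iqr",
    "mann_whitney_u",
    "categorical_test",
    "fisher_exact_rxc",
    "shapiro_wilk",
    "summarize_continuous",
    "summarize_categorical",
]

EXPECTED_COUNT_RULE = 5.0
ENUMERATION_MAX_TOTAL = 200
MC_SAMPLES = 20000


@dataclass(frozen=True)
class GroupSummary:
    """One row of a Table-1/Table-2-style group comparison."""

    variable: str
    normal: str
    abnormal: str
    test: str
    p: float
    n_normal: int
    n_abnormal: int


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation, missing excluded."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no non-missing values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p: exact enumeration for small
    untied samples, tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _log_table_prob(table: np.ndarray, row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    n = row_tot.sum()
    return float(
        gammaln(row_tot + 1).sum()
        + gammaln(col_tot + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_rxc(table: np.ndarray, seed: int = 0) -> float:
    """Two-sided Fisher exact p for an r x c table (probability rule).

    Full enumeration of tables sharing the observed margins when the
    grand total is at most 200; otherwise Monte-Carlo with a fixed seed.
    """
    table = np.asarray(table, dtype=int)
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    n = int(table.sum())
    if n == 0 or np.any(row_tot == 0) or np.any(col_tot == 0):
        return 1.0
    if table.shape == (2, 2):
        return fisher_exact(TwoByTwo(*table.ravel()))
    logp_obs = _log_table_prob(table, row_tot, col_tot)
    tol = 1e-9
    if n <= ENUMERATION_MAX_TOTAL:
        return _enumerate_p(table.shape, row_tot, col_tot, logp_obs + tol)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(table.shape[0]), row_tot)
    hits = 0
    for _ in range(MC_SAMPLES):
        perm = rng.permutation(labels)
        sim = np.zeros_like(table)
        start = 0
        for j, cj in enumerate(col_tot):
            rows, counts = np.unique(perm[start:start + cj], return_counts=True)
            sim[rows, j] = counts
            start += cj
        if _log_table_prob(sim, row_tot, col_tot) <= logp_obs + tol:
            hits += 1
    return (hits + 1) / (MC_SAMPLES + 1)


def _enumerate_p(shape, row_tot, col_tot, logp_cut) -> float:
    """Sum probabilities of all margin-consistent tables with log-prob
    below the cut; recursion over cells with capacity pruning."""
    r, c = shape
    n = int(row_tot.sum())
    log_const = float(gammaln(row_tot + 1).sum() + gammaln(col_tot + 1).sum() - gammaln(n + 1))
    total = 0.0
    cell = np.zeros((r, c), dtype=int)
    col_rem = col_tot.astype(int).copy()

    def rec(i: int, lg: float) -> None:
        nonlocal total
        if i == r - 1:
            # last row forced by the column margins
            if np.any(col_rem > row_tot[i]) or col_rem.sum() != row_tot[i]:
                return
            logp = log_const - lg - float(gammaln(col_rem + 1).sum())
            if logp <= logp_cut:
                total += math.exp(logp)
            return
        _fill_row(i, 0, int(row_tot[i]), lg)

    def _fill_row(i: int, j: int, rem: int, lg: float) -> None:
        if j == c - 1:
            if rem <= col_rem[j]:
                col_rem[j] -= rem
                rec(i + 1, lg + float(gammaln(rem + 1)))
                col_rem[j] += rem
            return
        for v in range(min(rem, int(col_rem[j])) + 1):
            col_rem[j] -= v
            _fill_row(i, j + 1, rem - v, lg + float(gammaln(v + 1)))
            col_rem[j] += v

    rec(0, 0.0)
    return min(1.0, total)


def categorical_test(table: np.ndarray, seed: int = 0) -> tuple[str, float]:
    """Chi-square when all expected counts >= 5, else Fisher exact.

    Degenerate tables (a zero margin) return p = 1.  The chi-square is
    the uncorrected Pearson statistic.
    """
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    n = table.sum()
    if n == 0 or np.any(row_tot == 0) or np.any(col_tot == 0):
        return "degenerate", 1.0
    expected = np.outer(row_tot, col_tot) / n
    if np.all(expected >= EXPECTED_COUNT_RULE):
        res = stats.chi2_contingency(table, correction=False)
        return "chi_square", float(res.pvalue)
    return "fisher_exact", fisher_exact_rxc(table, seed=seed)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (valid for 3 <= n <= 5000)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {arr.size}")
    if np.ptp(arr) == 0:
        return 0.0, 0.0  # degenerate constant sample: maximal non-normality
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def summarize_continuous(
    variable: str, normal_values: Sequence[float], abnormal_values: Sequence[float]
) -> GroupSummary:
    """Median (IQR) per group with a Mann-Whitney comparison."""
    m0, q10, q30 = median_iqr(normal_values)
    m1, q11, q31 = median_iqr(abnormal_values)
    _, p = mann_whitney_u(normal_values, abnormal_values)
    fmt = lambda m, a, b: f"{m:g} ({a:g}-{b:g})"
    n0 = int(np.sum(~np.isnan(np.asarray(normal_values, dtype=float))))
    n1 = int(np.sum(~np.isnan(np.asarray(abnormal_values, dtype=float))))
    return GroupSummary(variable, fmt(m0, q10, q30), fmt(m1, q11, q31),
                        "mann_whitney_u", p, n0, n1)


def summarize_categorical(
    variable: str, counts_normal: Sequence[int], counts_abnormal: Sequence[int],
    labels: Sequence[str], seed: int = 0,
) -> list[GroupSummary]:
    """n (%) rows per level with one shared categorical test p-value.

    Percentages are computed on the non-missing denominator of each
    group; the test contrasts the full level-by-group table.
    """
    counts_normal = np.asarray(counts_normal, dtype=int)
    counts_abnormal = np.asarray(counts_abnormal, dtype=int)
    table = np.column_stack([counts_normal, counts_abnormal])
    test, p = categorical_test(table, seed=seed)
    n0, n1 = counts_normal.sum(), counts_abnormal.sum()
    rows = []
    for lbl, c0, c1 in zip(labels, counts_normal, counts_abnormal):
        rows.append(
            GroupSummary(
                f"{variable}: {lbl}",
                f"{c0} ({100 * c0 / n0:.1f})" if n0 else "0",
                f"{c1} ({100 * c1 / n1:.1f})" if n1 else "0",
                test, p, int(n0), int(n1),
            )
        )
    return rows
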