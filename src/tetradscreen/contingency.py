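"""Exact and asymptotic inference on 2x2 tables.

Odds ratios use the cross-product with an optional Haldane-Anscombe
correction (0.5 added to *every* cell when any cell is zero); confidence
intervals use the Woolf logit form ``exp(ln OR +/- z * sqrt(1/a + 1/b +
1/c + 1/d))``.  A Koopman asymptotic-score interval for the risk ratio is
provided as a labelled alternative.  Fisher's exact two-sided p-value
follows the "probability at most that of the observed table" rule;
McNemar's test switches between the continuity-corrected chi-square (>= 10
discordant pairs) and the exact binomial version; binomial proportions get
exact Clopper-Pearson intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TwoByTwo",
    "PairedTable",
    "MetricCI",
    "DxAccuracy",
    "odds_ratio",
    "or_ci_logit",
    "koopman_rr_ci",
    "fisher_exact",
    "mcnemar",
    "clopper_pearson",
    "dx_accuracy",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts: a = exposed outcome+, b = exposed
    outcome-, c = unexposed outcome+, d = unexposed outcome-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class PairedTable:
    """Paired classification counts for two tests on the same subjects."""

    both_pos: int
    marker_only: int
    tetrad_only: int
    both_neg: int

    def __post_init__(self) -> None:
        if min(self.both_pos, self.marker_only, self.tetrad_only, self.both_neg) < 0:
            raise ValueError("paired counts must be non-negative")

    @property
    def discordant(self) -> int:
        return self.marker_only + self.tetrad_only


def _corrected(t: TwoByTwo, correct_zero: bool) -> tuple[float, float, float, float]:
    if correct_zero and t.has_zero:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
    return float(t.a), float(t.b), float(t.c), float(t.d)


def odds_ratio(t: TwoByTwo, correct_zero: bool = True) -> float:
    """Sample odds ratio (a*d)/(b*c), Haldane-Anscombe corrected when a
    zero cell is present and ``correct_zero`` is set."""
    a, b, c, d = _corrected(t, correct_zero)
    if b * c == 0:
        if a * d == 0:
            raise ValueError("odds ratio undefined: zero numerator and denominator")
        raise ValueError("odds ratio undefined: zero denominator (enable correct_zero)")
    return (a * d) / (b * c)


def or_ci_logit(
    t: TwoByTwo, level: float = 0.95, correct_zero: bool = True
) -> tuple[float, float]:
    """Woolf logit confidence interval for the odds ratio."""
    a, b, c, d = _corrected(t, correct_zero)
    if min(a, b, c, d) == 0:
        raise ValueError("logit interval undefined with a zero cell (enable correct_zero)")
    z = stats.norm.ppf(0.5 + level / 2)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def koopman_rr_ci(t: TwoByTwo, level: float = 0.95) -> tuple[float, float]:
    """Koopman asymptotic-score interval for the *risk ratio* p1/p0,
    with rows (a, b) exposed and (c, d) unexposed.

    Provided as the labelled alternative interval; it targets the risk
    ratio, not the odds ratio, and so does not reproduce logit OR CIs.
    """
    x1, n1 = t.a, t.a + t.b
    x0, n0 = t.c, t.c + t.d
    if n1 == 0 or n0 == 0:
        raise ValueError("both exposure rows must be non-empty")
    chi2_crit = stats.chi2.ppf(level, 1)

    def score(theta: float) -> float:
        # constrained MLE of p0 given RR = theta (Koopman / Miettinen-Nurminen);
        # the smaller quadratic root, in the numerically stable form
        a_ = theta * (n1 + n0)
        b_ = -(theta * (n1 + x0) + x1 + n0)
        c_ = x1 + x0
        p0 = 2 * c_ / (-b_ + math.sqrt(b_ * b_ - 4 * a_ * c_))
        p1 = p0 * theta
        num = 0.0
        if p1 > 0 and p1 < 1:
            num += (x1 - n1 * p1) ** 2 / (n1 * p1 * (1 - p1))
        if p0 > 0 and p0 < 1:
            num += (x0 - n0 * p0) ** 2 / (n0 * p0 * (1 - p0))
        return num - chi2_crit

    rr = ((x1 + 0.5) / (n1 + 0.5)) / ((x0 + 0.5) / (n0 + 0.5))
    lo = optimize.brentq(score, 1e-12, rr) if score(1e-12) > 0 else 0.0
    hi_bracket = rr
    while score(hi_bracket) < 0 and hi_bracket < 1e12:
        hi_bracket *= 10
    hi = optimize.brentq(score, rr, hi_bracket) if hi_bracket < 1e12 else math.inf
    return lo, hi


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p-value (hypergeometric, probability rule)."""
    if (t.a + t.b == 0 or t.c + t.d == 0) or (t.a + t.c == 0 or t.b + t.d == 0):
        return 1.0
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def mcnemar(p: PairedTable) -> tuple[Optional[float], float, str]:
    """McNemar's test on the discordant pairs.

    Returns ``(statistic, p, method)``: the continuity-corrected
    chi-square (1 df) when discordant pairs >= 10, the exact two-sided
    binomial p (statistic ``None``) for sparser tables, and a degenerate
    p = 1 when there are no discordant pairs.
    """
    m, t_ = p.marker_only, p.tetrad_only
    disc = m + t_
    if disc == 0:
        return None, 1.0, "degenerate"
    if disc >= 10:
        statistic = (abs(m - t_) - 1) ** 2 / disc
        return statistic, float(stats.chi2.sf(statistic, 1)), "chi2_cc"
    pval = min(1.0, 2.0 * float(stats.binom.cdf(min(m, t_), disc, 0.5)))
    return None, pval, "exact_binomial"


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson interval from beta quantiles."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError(f"need 0 <= successes <= n with n > 0, got {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


@dataclass(frozen=True)
class MetricCI:
    estimate: float
    lo: float
    hi: float


@dataclass(frozen=True)
class DxAccuracy:
    sensitivity: Optional[MetricCI]
    specificity: Optional[MetricCI]
    ppv: Optional[MetricCI]
    npv: Optional[MetricCI]
    accuracy: Optional[MetricCI]


def _metric(successes: int, denom: int, level: float) -> Optional[MetricCI]:
    if denom == 0:
        return None
    lo, hi = clopper_pearson(successes, denom, level)
    return MetricCI(successes / denom, lo, hi)


def dx_accuracy(tp: int, fp: int, fn: int, tn: int, level: float = 0.95) -> DxAccuracy:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    A metric whose denominator is empty is reported as ``None``; the
    others are still computed.
    """
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    return DxAccuracy(
        sensitivity=_metric(tp, tp + fn, level),
        specificity=_metric(tn, tn + fp, level),
        ppv=_metric(tp, tp + fp, level),
        npv=_metric(tn, tn + fn, level),
        accuracy=_metric(tp + tn, tp + fp + fn + tn, level),
    )
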