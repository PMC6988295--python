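"""Composite-score and univariate statistics.

Welch's heteroscedastic one-way ANOVA with Dunnett-T3-style pairwise
comparisons (Welch t statistics, Sidak family-wise adjustment), two-sample
t tests, Pearson correlation, and FDR-based robust outlier detection for a
single group of measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "PairwiseResult",
    "CorrelationResult",
    "welch_anova",
    "dunnett_t3",
    "two_sample_t",
    "pearson",
    "rout_outliers",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Figure-style significance markers: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    t_statistic: float
    df: float
    p_unadjusted: float
    p_adjusted: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


@dataclass
class GroupComparison:
    """Welch omnibus result plus pairwise table on one response variable."""

    groups: list[str]
    n: dict[str, int]
    means: dict[str, float]
    variances: dict[str, float]
    F_welch: float
    df1: float
    df2: float
    p_omnibus: float
    pairwise: list[PairwiseResult] = field(default_factory=list)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": pr.pair[0],
                "group_b": pr.pair[1],
                "t": pr.t_statistic,
                "df": pr.df,
                "p_unadjusted": pr.p_unadjusted,
                "p_adjusted": pr.p_adjusted,
                "stars": pr.stars,
            }
            for pr in self.pairwise
        ]
        return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _group_stats(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(pd.Series(groups).astype(str))
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups have different lengths")
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    n, m, v = {}, {}, {}
    for lv in levels:
        g = values[groups == lv]
        if len(g) < 2:
            raise ValueError(f"group {lv!r} has < 2 samples")
        var = float(np.var(g, ddof=1))
        if var == 0:
            raise ValueError(f"group {lv!r} has zero within-group variance")
        n[lv] = int(len(g))
        m[lv] = float(np.mean(g))
        v[lv] = var
    return levels, n, m, v


def welch_anova(values, groups) -> GroupComparison:
    """Welch's heteroscedastic one-way ANOVA.

    Uses variance-weighted group means (weights n_g / s_g^2) and a
    Satterthwaite-type denominator df; p from the F distribution.
    """
    levels, n, m, v = _group_stats(values, groups)
    k = len(levels)
    w = {lv: n[lv] / v[lv] for lv in levels}
    w_sum = sum(w.values())
    grand = sum(w[lv] * m[lv] for lv in levels) / w_sum
    A = sum(w[lv] * (m[lv] - grand) ** 2 for lv in levels) / (k - 1)
    h = sum((1 - w[lv] / w_sum) ** 2 / (n[lv] - 1) for lv in levels)
    B = 1 + 2 * (k - 2) / (k**2 - 1) * h
    F = A / B
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * h)
    p = float(sps.f.sf(F, df1, df2))
    return GroupComparison(
        groups=levels,
        n=n,
        means=m,
        variances=v,
        F_welch=float(F),
        df1=float(df1),
        df2=float(df2),
        p_omnibus=p,
    )


def dunnett_t3(values, groups, alpha: float = 0.05) -> GroupComparison:
    """All-pairs unequal-variance post hoc comparisons (Dunnett T3 style).

    Each pair gets a Welch t statistic with Welch-Satterthwaite df.  The
    family-wise adjustment approximates the studentized-maximum-modulus
    criterion with Sidak-adjusted two-sided t probabilities across the
    m = k(k-1)/2 comparisons; for independent statistics the two coincide,
    and under the positive dependence induced by shared groups the Sidak
    bound is conservative.
    """
    comp = welch_anova(values, groups)
    levels = comp.groups
    m_comp = len(levels) * (len(levels) - 1) // 2
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            t, df, p = _welch_t_from_stats(
                comp.means[a],
                comp.variances[a],
                comp.n[a],
                comp.means[b],
                comp.variances[b],
                comp.n[b],
            )
            p_adj = float(min(1.0, 1.0 - (1.0 - p) ** m_comp))
            comp.pairwise.append(
                PairwiseResult(
                    pair=(a, b),
                    t_statistic=t,
                    df=df,
                    p_unadjusted=p,
                    p_adjusted=p_adj,
                )
            )
    return comp


def _welch_t_from_stats(m1, v1, n1, m2, v2, n2):
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def two_sample_t(values_a, values_b, variant: str = "student"):
    """Two-sided two-sample t test.

    ``variant="student"`` pools variances; ``"welch"`` does not.
    Returns ``(t, df, p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero combined variance")
    if variant == "student":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(res.statistic), float(df), float(res.pvalue)


def pearson(scores, phenotype) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs have different lengths")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x), p=float(res.pvalue))


def rout_outliers(values, Q: float = 0.01) -> np.ndarray:
    """Robust FDR-based outlier detection for one group of measurements.

    Location is the median; robust scale (RSDR) is the 68.27th percentile of
    absolute residuals scaled by n/(n-1).  Each point's residual/RSDR is
    treated as a t statistic (df = n - 1) and tested with a Benjamini-
    Hochberg step-up sweep at level Q: the most extreme point is compared
    to Q/n, the least extreme to Q, and all points at least as extreme as
    the largest passing rank are flagged.  Returns a boolean mask of
    detected outliers.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for robust outlier detection")
    if not 0 < Q <= 0.1:
        raise ValueError("Q must be in (0, 0.1]")
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        # more than half the points identical; any deviant point is an outlier
        return resid != 0
    t = np.abs(resid) / rsdr
    p = 2 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p)  # most extreme first
    mask = np.zeros(n, dtype=bool)
    thresholds = Q * np.arange(1, n + 1) / n
    passing = np.nonzero(p[order] <= thresholds)[0]
    if len(passing):
        mask[order[: passing[-1] + 1]] = True
    return mask
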