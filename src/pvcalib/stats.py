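"""Group-contrast statistics for validity-calibration studies.

Independent and paired t-tests, Levene's homogeneity test, Cohen's d from
summary statistics, the pooled two-proportion z-test, Pearson correlation
with shared variance, and cumulative-frequency tables.  The inferential
machinery defers to scipy; the summary-statistic conventions that matter for
reproducing published tables (notably the equal-weighted pooled-SD form of
Cohen's d) are implemented here and documented on each function.

Alpha convention: all p-values are two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContrastResult:
    """One contrast: test statistic, df, two-tailed p, effect size, and
    group summaries.  Fields are None where undefined (degenerate input)."""

    test: str
    statistic: float | None
    df: float | tuple | None
    p: float | None
    d: float | None = None
    n1: int | None = None
    mean1: float | None = None
    sd1: float | None = None
    n2: int | None = None
    mean2: float | None = None
    sd2: float | None = None
    heteroscedastic: bool | None = None


def cohen_d_independent(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with the equal-weighted pooled SD, sqrt((s1^2 + s2^2)/2).

    This form weights the two group SDs equally regardless of group sizes.
    It is the convention that reproduces effect sizes printed alongside
    group means/SDs in the clinical performance-validity literature; at
    unbalanced n it differs from the n-weighted pooled form, so the choice
    matters and is deliberate.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    return (m1 - m2) / math.sqrt((s1 * s1 + s2 * s2) / 2)


def _clean(x) -> np.ndarray:
    a = np.asarray(pd.Series(x, dtype=float).dropna(), dtype=float)
    return a


def independent_t(
    x, y, variant: str = "pooled", check_variance: bool = True
) -> ContrastResult:
    """Independent-samples t-test (pooled-variance Student by default,
    ``variant="welch"`` available).

    When ``check_variance`` is set, Levene's test (mean-centered) at p < .05
    attaches a heteroscedasticity flag to the result instead of silently
    switching variants.
    """
    a, b = _clean(x), _clean(y)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    stat = None if math.isnan(res.statistic) else float(res.statistic)
    p = None if math.isnan(res.pvalue) else float(res.pvalue)
    df = len(a) + len(b) - 2 if variant == "pooled" else float(res.df)
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    d = cohen_d_independent(a.mean(), s1, b.mean(), s2) if s1 > 0 and s2 > 0 else None
    flag = None
    if check_variance:
        lev = levene(a, b)
        flag = lev.p is not None and lev.p < 0.05
    return ContrastResult(
        test=f"independent_t[{variant}]", statistic=stat, df=df, p=p, d=d,
        n1=len(a), mean1=float(a.mean()), sd1=float(s1),
        n2=len(b), mean2=float(b.mean()), sd2=float(s2),
        heteroscedastic=flag,
    )


def paired_t(x, y) -> ContrastResult:
    """Paired (repeated-measures) t-test on the within-pair differences,
    df = n - 1.  Zero-variance differences yield an undefined marker, and
    the reported effect size is mean(diff)/sd(diff)."""
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        raise ValueError("paired test needs n >= 2 complete pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return ContrastResult(
            test="paired_t", statistic=None, df=n - 1, p=None, d=None,
            n1=n, mean1=float(a.mean()), sd1=float(a.std(ddof=1)),
            n2=n, mean2=float(b.mean()), sd2=float(b.std(ddof=1)),
        )
    res = sps.ttest_rel(a, b)
    return ContrastResult(
        test="paired_t", statistic=float(res.statistic), df=n - 1,
        p=float(res.pvalue), d=float(diff.mean() / sd),
        n1=n, mean1=float(a.mean()), sd1=float(a.std(ddof=1)),
        n2=n, mean2=float(b.mean()), sd2=float(b.std(ddof=1)),
    )


def levene(x, y) -> ContrastResult:
    """Levene's test of homogeneity of variance, mean-centered: a one-way
    ANOVA on absolute deviations from each group's mean."""
    a, b = _clean(x), _clean(y)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    if za.std(ddof=1) == 0 and zb.std(ddof=1) == 0:
        return ContrastResult(
            test="levene", statistic=None, df=(1, len(a) + len(b) - 2), p=None,
            n1=len(a), sd1=float(a.std(ddof=1)), n2=len(b), sd2=float(b.std(ddof=1)),
        )
    res = sps.levene(a, b, center="mean")
    return ContrastResult(
        test="levene", statistic=float(res.statistic),
        df=(1, len(a) + len(b) - 2), p=float(res.pvalue),
        n1=len(a), sd1=float(a.std(ddof=1)), n2=len(b), sd2=float(b.std(ddof=1)),
    )


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ContrastResult:
    """Pooled two-proportion z-test:
    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.

    Undefined (None statistic) when the pooled proportion is 0 or 1.
    ``mean1``/``mean2`` on the result carry the two sample proportions.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n, n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ContrastResult(
            test="two_proportion_z", statistic=None, df=None, p=None,
            n1=n1, mean1=p1, n2=n2, mean2=p2,
        )
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * sps.norm.sf(abs(z))
    return ContrastResult(
        test="two_proportion_z", statistic=z, df=None, p=p,
        n1=n1, mean1=p1, n2=n2, mean2=p2,
    )


def base_rate_ratio(x1: int, n1: int, x2: int, n2: int) -> float | None:
    """Ratio of two failure base rates, p1/p2 (None when p2 is zero)."""
    p1, p2 = x1 / n1, x2 / n2
    return None if p2 == 0 else p1 / p2


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    r2: float | None
    p: float | None
    n: int


def pearson_r(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with shared variance (r^2) and a
    two-tailed p.  Pairs with a missing value are dropped; zero variance in
    either variable yields an undefined marker."""
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if len(a) != len(b):
        raise ValueError("samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 3 or a.std() == 0 or b.std() == 0:
        return CorrelationResult(None, None, None, n)
    res = sps.pearsonr(a, b)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), n)


@dataclass(frozen=True)
class DistributionRow:
    """One support point: count, cumulative percentage at or below the
    score, and conditional means of auxiliary measures among records at
    exactly that score."""

    score: int
    n: int
    pct_cum: float
    aux_means: dict


def cumulative_table(
    scores,
    support: Sequence[int],
    aux: Mapping[str, Sequence[float]] | None = None,
) -> list[DistributionRow]:
    """Cumulative-percentage table of integer scores over ``support``.

    ``pct_cum`` at score s is 100 * P(score <= s); it is non-decreasing and
    reaches 100.0 at the maximum observed score.  ``aux`` maps names to
    values aligned with ``scores``; conditional means are NaN where a score
    level is unoccupied.
    """
    raw = np.asarray(list(scores), dtype=float)
    s = raw[~np.isnan(raw)]
    support = list(support)
    if len(s) and (s.min() < min(support) or s.max() > max(support)):
        raise ValueError("scores outside the declared support")
    aux = aux or {}
    aux_arr = {k: np.asarray(list(v), dtype=float) for k, v in aux.items()}
    total = len(s)
    rows = []
    for point in support:
        at = s == point
        n_at = int(at.sum())
        cum = 100.0 * float((s <= point).sum()) / total if total else math.nan
        means = {}
        for k, v in aux_arr.items():
            vals = v[raw == point]
            vals = vals[~np.isnan(vals)]
            means[k] = float(vals.mean()) if len(vals) else math.nan
        rows.append(DistributionRow(score=point, n=n_at, pct_cum=cum, aux_means=means))
    return rows


def cumulative_frame(rows: Sequence[DistributionRow]) -> pd.DataFrame:
    data = []
    for r in rows:
        rec = {"score": r.score, "n": r.n, "pct_cum": r.pct_cum}
        rec.update({f"mean_{k}": v for k, v in r.aux_means.items()})
        data.append(rec)
    return pd.DataFrame(data)


def contrasts_frame(results: Mapping[str, ContrastResult]) -> pd.DataFrame:
    """Tidy one-row-per-contrast CSV-exportable view."""
    rows = []
    for label, r in results.items():
        rows.append(
            {
                "contrast": label, "test": r.test, "statistic": r.statistic,
                "df": str(r.df) if isinstance(r.df, tuple) else r.df,
                "p": r.p, "d": r.d,
                "n1": r.n1, "mean1": r.mean1, "sd1": r.sd1,
                "n2": r.n2, "mean2": r.mean2, "sd2": r.sd2,
                "heteroscedastic": r.heteroscedastic,
            }
        )
    return pd.DataFrame(rows)
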