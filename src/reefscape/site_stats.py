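"""Frequentist site comparisons for structural metrics and body sizes.

Implements the heteroscedasticity-robust one-way toolkit: Levene's test
(Brown-Forsythe median centering by default), Welch's ANOVA with
Welch-Satterthwaite degrees of freedom, the Games-Howell pairwise post hoc
built on the studentized-range distribution, and the classical one-way
ANOVA used for body-length comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "PairwiseResult",
    "levene_test",
    "welch_anova",
    "games_howell",
    "one_way_anova",
]


@dataclass(frozen=True)
class TestResult:
    """One-way test summary: statistic, (possibly fractional) dfs, p-value."""

    statistic: float
    df1: float
    df2: float
    p_value: float
    group_means: tuple[float, ...] = field(default=())
    group_sds: tuple[float, ...] = field(default=())
    group_ns: tuple[int, ...] = field(default=())
    method: str = ""


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[int, int]
    statistic: float
    df: float
    p_value: float
    mean_difference: float


def _prep_groups(groups, min_n: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(gs):
        if g.size < min_n:
            raise ValueError(f"group {i} has fewer than {min_n} observations")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return gs


def _summaries(gs):
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    variances = np.array([g.var(ddof=1) for g in gs])
    return ns, means, variances


def levene_test(groups, center: str = "median") -> TestResult:
    """Levene's test for equal variances across groups.

    One-way ANOVA on absolute deviations from the group center; ``center``
    'median' gives the Brown-Forsythe variant (default), 'mean' the
    original form.
    """
    gs = _prep_groups(groups)
    if center not in {"median", "mean"}:
        raise ValueError("center must be 'median' or 'mean'")
    centers = [np.median(g) if center == "median" else g.mean() for g in gs]
    devs = [np.abs(g - c) for g, c in zip(gs, centers)]
    ns, means, variances = _summaries(devs)
    if np.all(variances == 0):
        raise ValueError("degenerate groups: zero spread in absolute deviations")
    return _classic_f(devs, method=f"Levene ({center}-centered)")


def _classic_f(gs, method: str) -> TestResult:
    ns, means, variances = _summaries(gs)
    k = len(gs)
    n_total = ns.sum()
    grand = np.concatenate(gs).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * variances).sum())
    df1, df2 = k - 1, n_total - k
    if df2 <= 0:
        raise ValueError("no within-group degrees of freedom")
    if ss_within == 0:
        raise ValueError("degenerate groups: zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(
        float(f), float(df1), float(df2), p,
        tuple(means), tuple(np.sqrt(variances)), tuple(int(n) for n in ns),
        method,
    )


def one_way_anova(groups) -> TestResult:
    """Classical one-way ANOVA (equal-variance F test)."""
    gs = _prep_groups(groups)
    return _classic_f(gs, method="one-way ANOVA")


def welch_anova(groups) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    Groups are weighted by ``n_i / s_i^2``; the denominator degrees of
    freedom follow Welch-Satterthwaite and are generally fractional.
    """
    gs = _prep_groups(groups)
    ns, means, variances = _summaries(gs)
    if np.any(variances == 0):
        raise ValueError("zero within-group variance; Welch weights undefined")
    k = len(gs)
    w = ns / variances
    w_sum = w.sum()
    grand = float((w * means).sum() / w_sum)
    num = float((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = float((((1 - w / w_sum) ** 2) / (ns - 1)).sum())
    den = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * lam
    f = num / den
    df1 = k - 1
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(
        float(f), float(df1), float(df2), p,
        tuple(means), tuple(np.sqrt(variances)), tuple(int(n) for n in ns),
        "Welch's ANOVA",
    )


def games_howell(groups) -> list[PairwiseResult]:
    """Games-Howell pairwise comparisons for unequal variances.

    For each pair, ``t = (m_i - m_j) / sqrt(s_i^2/n_i + s_j^2/n_j)`` with
    pairwise Welch degrees of freedom; the p-value comes from the
    studentized-range distribution with ``q = t * sqrt(2)`` and the total
    number of groups.
    """
    gs = _prep_groups(groups)
    ns, means, variances = _summaries(gs)
    if np.any(variances == 0):
        raise ValueError("zero within-group variance; Games-Howell undefined")
    k = len(gs)
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variances[i] / ns[i], variances[j] / ns[j]
            se = np.sqrt(vi + vj)
            diff = means[i] - means[j]
            t = diff / se
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            q = abs(t) * np.sqrt(2.0)
            p = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
            out.append(PairwiseResult((i, j), float(t), float(df), p, float(diff)))
    return out
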