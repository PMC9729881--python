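"""Comparative statistics across animal groups.

Wraps the classical tests used to compare per-section/per-animal summaries
(portal density, modelled lobule area, class densities) between groups:
one-way ANOVA with Tukey HSD post hoc, Kruskal–Wallis, Spearman rank
correlation, and two-sample t-tests (Welch by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "one_way_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "spearman",
    "two_sample_ttest",
]


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    p_value: float
    df: tuple[float, ...] | None = None
    pairwise: dict[tuple[str, str], float] | None = None
    flags: list[str] = field(default_factory=list)


def _check_groups(samples: Mapping[str, Sequence[float]], min_size: int = 2):
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in arrs.items():
        if len(v) < min_size:
            raise ValueError(f"group {k!r} has fewer than {min_size} observations")
    return arrs


def one_way_anova(samples: Mapping[str, Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with df (k−1, N−k); p from the F
    distribution.  Zero within-group variance with equal group means makes
    F undefined (0/0) and is flagged.
    """
    arrs = _check_groups(samples)
    groups = list(arrs.values())
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = (k - 1, n_total - k)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(
                "one_way_anova", math.nan, math.nan, df, flags=["F_undefined"]
            )
        return TestResult("one_way_anova", math.inf, 0.0, df, flags=["zero_within_variance"])
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(F, *df))
    return TestResult("one_way_anova", float(F), p, df)


def tukey_hsd(samples: Mapping[str, Sequence[float]]) -> TestResult:
    """Tukey HSD pairwise comparisons (Tukey–Kramer for unbalanced groups).

    The reported scalar statistic/p is the smallest adjusted pairwise p
    with its studentized-range statistic; all pairwise adjusted p-values
    are in ``pairwise``.
    """
    arrs = _check_groups(samples)
    labels = list(arrs.keys())
    res = sps.tukey_hsd(*arrs.values())
    pairwise = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        pairwise[(labels[i], labels[j])] = float(res.pvalue[i, j])
    (best_pair, best_p) = min(pairwise.items(), key=lambda kv: kv[1])
    i, j = labels.index(best_pair[0]), labels.index(best_pair[1])
    return TestResult(
        "tukey_hsd",
        statistic=float(res.statistic[i, j]),
        p_value=best_p,
        pairwise=pairwise,
    )


def kruskal_wallis(samples: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank test with tie correction; chi² p with df = k−1."""
    arrs = _check_groups(samples)
    k = len(arrs)
    pooled = np.concatenate(list(arrs.values()))
    if np.all(pooled == pooled[0]):
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, (k - 1,), flags=["all_identical"]
        )
    H, p = sps.kruskal(*arrs.values())
    return TestResult("kruskal_wallis", float(H), float(p), (k - 1,))


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t_approx"
) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties).

    p by the t-approximation on n−2 df (default) or, with
    ``method="exact"`` and n ≤ 10, by full enumeration of rank
    permutations.  A constant input leaves rho undefined (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", math.nan, math.nan, (n - 2,), flags=["constant_input"])
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 10:
            raise ValueError("exact method supported only for n <= 10")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return TestResult("spearman", rho, count / total, (n - 2,))
    if abs(rho) >= 1.0:
        return TestResult("spearman", rho, 0.0, (n - 2,))
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return TestResult("spearman", rho, p, (n - 2,))


def two_sample_ttest(
    a: Sequence[float],
    b: Sequence[float],
    two_tailed: bool = True,
    equal_var: bool = False,
) -> TestResult:
    """Two-sample t-test, Welch (unequal variance) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("t_test", 0.0, 1.0, flags=["degenerate_variance"])
        return TestResult("t_test", math.inf, 0.0, flags=["degenerate_variance"])
    alternative = "two-sided" if two_tailed else "greater"
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return TestResult("t_test", float(res.statistic), float(res.pvalue), (float(res.df),))
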