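"""Group comparisons and boxplot summaries.

Test selection is a fixed assignment, not a data-driven gate: nucleus
size (approximately normal) is compared with a two-sample t-test
(Welch's unequal-variance variant by default) and every other metric
with the Kruskal-Wallis rank test (used even for two groups, with tie
correction). An optional Shapiro-Wilk normality gate exists but is off
by default. Raw pairwise p-values are reported without multiple-testing
correction; Holm adjustment is available as an opt-in column.

Significance tiers: n.s. (p >= 0.05), * (p < 0.05), ** (p < 0.01),
*** (p < 0.001).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class Tier(enum.Enum):
    NS = "n.s."
    STAR = "*"
    STAR2 = "**"
    STAR3 = "***"


class TestUsed(enum.Enum):
    TWO_SAMPLE_T = "two_sample_t"
    KRUSKAL_WALLIS = "kruskal_wallis"


class MetricKind(enum.Enum):
    NUCLEUS_SIZE = "nucleus_size"
    OTHER = "other"


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    group_labels: tuple[str, ...]
    test_used: TestUsed
    statistic: float
    p_value: float
    tier: Tier


@dataclass(frozen=True)
class BoxplotSummary:
    """Distribution summary matching the reporting convention: median,
    quartiles (linear-interpolation quantiles), mean, whiskers at
    mean +/- 2 sample SD, and the values outside the whiskers as
    outliers."""

    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def significance_tier(p: float) -> Tier:
    """Map a p-value to its significance tier (boundaries: a p of
    exactly 0.05 is non-significant; strict < at every level)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return Tier.STAR3
    if p < 0.01:
        return Tier.STAR2
    if p < 0.05:
        return Tier.STAR
    return Tier.NS


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    metric_kind: MetricKind,
    metric_name: str = "",
    equal_var: bool = False,
    normality_gate: bool = False,
) -> GroupComparison:
    """Compare groups of per-nucleus values.

    NUCLEUS_SIZE metrics use the two-sample t-test (Welch by default;
    ``equal_var=True`` for the pooled-variance variant) and require
    exactly two groups; everything else uses Kruskal-Wallis, which
    accepts two or more groups. Each group needs at least 3 values.
    With ``normality_gate`` a Shapiro-Wilk check (alpha 0.05, any group
    failing) demotes a t-test request to Kruskal-Wallis.
    """
    labels = tuple(values_by_group.keys())
    groups = [np.asarray(values_by_group[lab], dtype=np.float64) for lab in labels]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for lab, g in zip(labels, groups):
        if g.size < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 values")

    use_t = metric_kind is MetricKind.NUCLEUS_SIZE
    if use_t and normality_gate:
        if any(stats.shapiro(g).pvalue < 0.05 for g in groups):
            use_t = False

    if use_t:
        if len(groups) != 2:
            raise ValueError("the two-sample t-test compares exactly two groups")
        a, b = groups
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # degenerate zero-variance groups: identical -> no evidence
            p = 1.0 if a.mean() == b.mean() else 0.0
            stat = 0.0 if p == 1.0 else np.inf
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            stat, p = float(res.statistic), float(res.pvalue)
        test = TestUsed.TWO_SAMPLE_T
    else:
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            # every observation tied: no rank information, no evidence
            stat, p = 0.0, 1.0
        else:
            res = stats.kruskal(*groups)
            stat, p = float(res.statistic), float(res.pvalue)
        test = TestUsed.KRUSKAL_WALLIS

    return GroupComparison(
        metric_name=metric_name,
        group_labels=labels,
        test_used=test,
        statistic=stat,
        p_value=p,
        tier=significance_tier(p),
    )


def pairwise_comparisons(
    values_by_group: Mapping[str, Sequence[float]],
    metric_kind: MetricKind,
    metric_name: str = "",
    holm: bool = False,
) -> list[GroupComparison]:
    """All pairwise group comparisons for one metric (raw p-values;
    Holm-adjusted tiers replace the raw ones when ``holm`` is set)."""
    labels = list(values_by_group.keys())
    out = [
        compare_groups(
            {a: values_by_group[a], b: values_by_group[b]}, metric_kind, metric_name
        )
        for a, b in itertools.combinations(labels, 2)
    ]
    if holm and out:
        ps = np.array([c.p_value for c in out])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        out = [
            GroupComparison(
                metric_name=c.metric_name,
                group_labels=c.group_labels,
                test_used=c.test_used,
                statistic=c.statistic,
                p_value=float(adj[i]),
                tier=significance_tier(float(adj[i])),
            )
            for i, c in enumerate(out)
        ]
    return out


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Median, quartiles, mean, +/- 2 SD whiskers and outliers."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    lo, hi = mean - 2 * sd, mean + 2 * sd
    outliers = tuple(float(x) for x in v[(v < lo) | (v > hi)])
    return BoxplotSummary(
        n=int(v.size),
        median=float(np.median(v)),
        q1=float(np.quantile(v, 0.25)),
        q3=float(np.quantile(v, 0.75)),
        mean=mean,
        sd=sd,
        whisker_lo=lo,
        whisker_hi=hi,
        outliers=outliers,
    )
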