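"""Group-wise rank statistics for termination metrics.

Covers the genome-wide comparisons of the termination analysis: Spearman
correlation of U4-tract number against TTE, pairwise Wilcoxon rank-sum tests
between U4/TTE groups, per-group median/quartile summaries, and the fraction
of TUs whose termination depends on the factor (TQRR < 1).

The rank-sum test switches between an exhaustive-enumeration exact p-value
(small samples, n+m ≤ 12) and the normal approximation with tie correction
(larger samples, via scipy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .termination_metrics import TerminationMetrics

__all__ = [
    "GroupSummary",
    "spearman",
    "rank_sum_test",
    "group_summaries",
    "dependency_fractions",
    "pairwise_rank_sum",
    "format_pvalue",
]

P_FLOOR = 2.2e-16  # conventional floor used in text output


@dataclass
class GroupSummary:
    group_label: str
    n: int
    median: float | None
    q1: float | None
    q3: float | None
    fraction_tqrr_lt1: float | None


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments.

    Midranks handle ties; the two-sided p is the permutation probability of a
    U statistic at least as far from its mean nm/2 as the observed one.
    """
    pooled = np.asarray(list(a) + list(b), float)
    n, m = len(a), len(b)
    ranks = sps.rankdata(pooled)
    mu = n * m / 2
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n + m), n):
        u = float(ranks[list(idx)].sum() - n * (n + 1) / 2)
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exhaustive enumeration for n+m ≤ 12, otherwise the normal approximation
    with tie correction and continuity correction.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(a) + len(b) <= 12:
        return _exact_rank_sum_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def format_pvalue(p: float) -> str:
    """Text rendering with the conventional '< 2.2e-16' floor."""
    return "< 2.2e-16" if p < P_FLOOR else f"{p:.3g}"


_GROUP_ORDERS = {
    "u4_group": ["0", "1", "2", ">2"],
    "tte_group": ["low", "medium", "high"],
    "dependency_class": ["highly", "moderately", "non"],
}


def group_summaries(metrics: Sequence[TerminationMetrics], grouping: str,
                    value_field: str = "tte_wt") -> list[GroupSummary]:
    """Per-group n, median, quartiles (linear interpolation) and the fraction
    of members with TQRR < 1.  Records with an undefined grouping label or
    value are excluded; empty groups are emitted with n=0 and None quantiles.
    """
    if grouping not in _GROUP_ORDERS:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = []
    for label in _GROUP_ORDERS[grouping]:
        members = [m for m in metrics if getattr(m, grouping) == label]
        values = [getattr(m, value_field) for m in members
                  if getattr(m, value_field) is not None]
        tqrrs = [m.tqrr for m in members if m.tqrr is not None]
        if values:
            q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7
            out.append(GroupSummary(
                label, len(values), float(med), float(q1), float(q3),
                (sum(t < 1 for t in tqrrs) / len(tqrrs)) if tqrrs else None))
        else:
            out.append(GroupSummary(label, 0, None, None, None, None))
    return out


def dependency_fractions(metrics: Sequence[TerminationMetrics],
                         ) -> tuple[float, dict[str, float]]:
    """Fraction of evaluable TUs with TQRR < 1, overall and by U4 group.

    ``by_group`` also carries the derived unions '>=1' and '>=2' over the
    four-way U4 partition.
    """
    evaluable = [m for m in metrics if m.tqrr is not None]
    if not evaluable:
        raise ValueError("no evaluable TQRR values")
    overall = sum(m.tqrr < 1 for m in evaluable) / len(evaluable)
    by_group: dict[str, float] = {}

    def frac(sub: list[TerminationMetrics]) -> float | None:
        return (sum(m.tqrr < 1 for m in sub) / len(sub)) if sub else None

    for label in _GROUP_ORDERS["u4_group"]:
        sub = [m for m in evaluable if m.u4_group == label]
        f = frac(sub)
        if f is not None:
            by_group[label] = f
    unions = {
        ">=1": [m for m in evaluable
                if m.u4_count is not None and m.u4_count >= 1],
        ">=2": [m for m in evaluable
                if m.u4_count is not None and m.u4_count >= 2],
    }
    for label, sub in unions.items():
        f = frac(sub)
        if f is not None:
            by_group[label] = f
    return overall, by_group


def pairwise_rank_sum(metrics: Sequence[TerminationMetrics], grouping: str,
                      value_field: str = "tte_wt",
                      holm: bool = False) -> dict[str, float]:
    """Raw pairwise Wilcoxon p-values between all group pairs.

    Holm correction is available by flag; the default reports raw p-values.
    """
    groups: dict[str, list[float]] = {}
    for label in _GROUP_ORDERS[grouping]:
        vals = [getattr(m, value_field) for m in metrics
                if getattr(m, grouping) == label
                and getattr(m, value_field) is not None]
        if vals:
            groups[label] = vals
    labels = list(groups)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    ps = {f"{a} vs {b}": rank_sum_test(groups[a], groups[b])
          for a, b in pairs}
    if holm and ps:
        keys = sorted(ps, key=ps.get)
        k = len(keys)
        adj, running = {}, 0.0
        for i, key in enumerate(keys):
            running = max(running, min(1.0, (k - i) * ps[key]))
            adj[key] = running
        ps = adj
    return ps
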