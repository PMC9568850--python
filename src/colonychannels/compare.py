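"""Nonparametric comparison of widths and areas across growth conditions.

Channel-width and base-area distributions are typically non-normal with
unequal group sizes, so groups are compared with the two-sided Mann-Whitney
U rank test; p < 0.05 is the conventional significance level and no
multiple-testing correction is applied (a caveat when many positions are
tested). Distribution summaries follow the standard boxplot conventions:
quartiles by linear interpolation, whiskers at 1.5 x IQR beyond the
quartiles, clamped to the observed data range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "mann_whitney_u", "summarise_group", "pairwise_compare"]

#: Largest n_a * n_b for which the exact null distribution is enumerated.
EXACT_LIMIT = 400


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_a, p-value).

    Midranks handle ties. The exact null distribution is used for small
    tie-free samples (n_a * n_b <= 400); otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size * b.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def summarise_group(values) -> GroupSummary:
    """Boxplot-style summary of one group's values."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(max(q1 - 1.5 * iqr, x.min())),
        whisker_high=float(min(q3 + 1.5 * iqr, x.max())),
    )


def pairwise_compare(
    table: pd.DataFrame, value_col: str, group_col: str
) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons between groups in a table."""
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for ga, gb in combinations(groups, 2):
        va = table.loc[table[group_col] == ga, value_col].to_numpy()
        vb = table.loc[table[group_col] == gb, value_col].to_numpy()
        if va.size == 0 or vb.size == 0:
            raise ValueError(f"group without data: {ga if va.size == 0 else gb}")
        u, p = mann_whitney_u(va, vb)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": va.size,
                "n_b": vb.size,
                "U": u,
                "p": p,
                "mean_ratio": float(va.mean() / vb.mean()) if vb.mean() != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
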