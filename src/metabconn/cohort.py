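"""Demographic cohort statistics.

Chi-square goodness-of-fit for group counts and pooled-variance two-sample
Student t-tests, computable either from raw columns or from printed
summary statistics (mean ± sd, n) alone — so published demographic tables
can be checked without the underlying data.

Choices fixed here: the t-test pools variances (not Welch) and the
chi-square uses no continuity correction; both match the conventions of
standard demographic tables in this literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "chi_square_equal_proportions",
    "two_sample_t_from_summary",
    "two_sample_t_from_raw",
    "summarize_participants",
    "format_table1",
]


@dataclass(frozen=True)
class GroupSummary:
    """(mean, sample sd, n) triple for one group, as printed in a table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group must have n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_data(cls, values: np.ndarray) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(mean=float(values.mean()), sd=float(values.std(ddof=1)),
                   n=int(values.size))


def chi_square_equal_proportions(counts) -> tuple[float, int, float]:
    """Goodness-of-fit of category counts against equal proportions.

    No continuity correction; df = k − 1; p from the chi-square upper tail.
    Returns (chi2, df, p).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if np.any(counts < 0) or np.any(counts != np.rint(counts)):
        raise ValueError("counts must be non-negative integers")
    total = counts.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    expected = total / counts.size
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = counts.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def two_sample_t_from_summary(
    a: GroupSummary, b: GroupSummary
) -> tuple[float, int, float]:
    """Pooled-variance Student t-test from two (mean, sd, n) summaries.

    sp² = ((n1−1)s1² + (n2−1)s2²) / (n1+n2−2);
    t = (m1−m2) / (sp · sqrt(1/n1 + 1/n2));  df = n1+n2−2; two-sided p.
    Returns (t, df, p).
    """
    if a.n + b.n < 4:
        raise ValueError("need a.n + b.n >= 4")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    denom = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if denom == 0:
        warnings.warn("zero pooled variance; t undefined, reported as 0",
                      UserWarning, stacklevel=2)
        return 0.0, df, 1.0
    t = float((a.mean - b.mean) / denom)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def two_sample_t_from_raw(x, y) -> tuple[float, int, float]:
    """Pooled t-test on raw samples; exactly equals the summary-based path."""
    return two_sample_t_from_summary(GroupSummary.from_data(x),
                                     GroupSummary.from_data(y))


def summarize_participants(
    participants: pd.DataFrame,
    group_column: str,
    numeric_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Demographics table split by a two-level group column.

    One row per variable: per-group mean ± sd (or counts for the group row),
    with a chi-square p for the counts and a pooled-t p for each numeric
    column.  Mirrors the usual "Table 1" layout of cohort studies.
    """
    levels = sorted(pd.unique(participants[group_column].astype(str)))
    if len(levels) != 2:
        raise ValueError(
            f"group column {group_column!r} must have exactly 2 levels, got {levels}"
        )
    g0 = participants[participants[group_column].astype(str) == levels[0]]
    g1 = participants[participants[group_column].astype(str) == levels[1]]
    if numeric_columns is None:
        numeric_columns = [
            c
            for c in participants.columns
            if c != group_column
            and pd.api.types.is_numeric_dtype(participants[c])
            and participants[c].nunique() > 1
        ]

    _, _, p_count = chi_square_equal_proportions([len(g0), len(g1)])
    rows = [
        {
            "variable": "count",
            levels[0]: f"{len(g0)}",
            levels[1]: f"{len(g1)}",
            "test": "chi-square",
            "p": p_count,
        }
    ]
    for col in numeric_columns:
        x = g0[col].to_numpy(dtype=float)
        y = g1[col].to_numpy(dtype=float)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, _, p = two_sample_t_from_raw(x, y)
        rows.append(
            {
                "variable": col,
                levels[0]: f"{x.mean():.2f} ± {x.std(ddof=1):.3f}",
                levels[1]: f"{y.mean():.2f} ± {y.std(ddof=1):.3f}",
                "test": "pooled t",
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def format_table1(table: pd.DataFrame) -> str:
    """Plain-text rendering of a summarize_participants table."""
    out = table.copy()
    out["p"] = out["p"].map(lambda v: f"{v:.3f}")
    return out.to_string(index=False)
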