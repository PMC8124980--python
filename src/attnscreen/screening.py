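"""Group screening statistics over per-level attention summaries.

The screening question is whether two groups of players (e.g. ADHD-like
vs control-like, or game completers vs non-completers) differ in mean
attention within each game level.  Each level is tested with a pooled-
variance (Student) two-sample t-test — degrees of freedom
``n1 + n2 - 2`` — with two-sided p-values, and the family of per-level
tests is controlled at a family-wise level with the Bonferroni rule
(reject when ``p <= alpha / m`` over the ``m`` levels).

Subjects who never entered a level contribute no value to that level's
comparison; a level where either group has fewer than two such subjects
is reported as not testable rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectRecord

__all__ = [
    "TTestResult",
    "GroupComparison",
    "two_sample_t",
    "critical_t",
    "bonferroni",
    "compare_by_level",
    "completion_split",
    "contingency_summary",
    "comparisons_to_frame",
]


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def two_sample_t(values1: Sequence[float], values2: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t-test with a two-sided p-value.

    ``t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2))`` with the pooled variance
    ``s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)`` and
    ``df = n1 + n2 - 2``.  Two identical-variance-zero groups with equal
    means give ``t = 0, p = 1``; zero pooled variance with unequal means
    is rejected as degenerate.
    """
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError(
            f"each group needs at least two values (got {x1.size} and {x2.size})"
        )
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("group values must be finite")
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    m1, m2 = x1.mean(), x2.mean()
    pooled_var = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    if pooled_var == 0.0:
        if m1 == m2:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = (m1 - m2) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def critical_t(alpha: float, df: int) -> float:
    """Two-sided critical value: the ``1 - alpha/2`` Student-t quantile."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Family-wise decisions: reject test i iff ``p_i <= alpha / m``."""
    p = list(p_values)
    if len(p) == 0:
        raise ValueError("p_values must be non-empty")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"p-values must lie in [0, 1], got {v}")
    threshold = alpha / len(p)
    return [v <= threshold for v in p]


@dataclass(frozen=True)
class GroupComparison:
    """One per-level two-group comparison (or a not-testable placeholder)."""

    level: int
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t: float
    df: int
    p: float
    significant_raw: bool
    significant_bonferroni: bool
    testable: bool = True


def compare_by_level(
    records: Iterable[SubjectRecord],
    key: Callable[[SubjectRecord], str] | None = None,
    groups: tuple[str, str] | None = None,
    alpha: float = 0.05,
    n_levels: int = 5,
) -> list[GroupComparison]:
    """Per-level group comparison with Bonferroni control across levels.

    ``key`` labels each subject (default: its ``group`` attribute) and
    ``groups`` fixes the (group1, group2) order; by default the two labels
    found are used in sorted order with ``"control"`` preferred first.
    Only subjects whose session entered a level contribute to that level;
    the Bonferroni family size is ``n_levels`` regardless of how many
    levels end up testable.
    """
    recs = list(records)
    if not recs:
        raise ValueError("empty cohort")
    if key is None:
        key = lambda r: r.group
    labels = [key(r) for r in recs]
    if groups is None:
        uniq = sorted(set(labels), key=lambda g: (g != "control", g))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two group labels, got {uniq}")
        groups = (uniq[0], uniq[1])
    g1, g2 = groups

    out: list[GroupComparison] = []
    threshold = alpha / n_levels
    for lvl in range(n_levels):
        v1 = [r.level_means[lvl] for r, lab in zip(recs, labels) if lab == g1 and lvl in r.level_means]
        v2 = [r.level_means[lvl] for r, lab in zip(recs, labels) if lab == g2 and lvl in r.level_means]
        if len(v1) < 2 or len(v2) < 2:
            out.append(
                GroupComparison(
                    level=lvl, group1=g1, group2=g2, n1=len(v1), n2=len(v2),
                    mean1=float(np.mean(v1)) if v1 else float("nan"),
                    mean2=float(np.mean(v2)) if v2 else float("nan"),
                    t=float("nan"), df=0, p=float("nan"),
                    significant_raw=False, significant_bonferroni=False,
                    testable=False,
                )
            )
            continue
        res = two_sample_t(v1, v2)
        out.append(
            GroupComparison(
                level=lvl, group1=g1, group2=g2, n1=len(v1), n2=len(v2),
                mean1=float(np.mean(v1)), mean2=float(np.mean(v2)),
                t=res.t, df=res.df, p=res.p,
                significant_raw=res.p <= alpha,
                significant_bonferroni=res.p <= threshold,
            )
        )
    return out


def completion_split(
    records: Iterable[SubjectRecord],
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition a cohort into (completed, uncompleted) by the session flag."""
    recs = list(records)
    if not recs:
        raise ValueError("empty cohort")
    done = [r for r in recs if r.completed]
    not_done = [r for r in recs if not r.completed]
    return done, not_done


def contingency_summary(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Counts of effective/ineffective and impulsive/non-impulsive subjects
    in each (group x completion) cell, with per-group totals.

    Effectiveness and impulsivity are two separate dichotomies of the same
    subjects, so within a row ``effective + ineffective`` and
    ``impulsive + non_impulsive`` each sum to the row total (plus the
    ``unclassified`` column, present only when some subject carries no
    CARAS classification).
    """
    recs = list(records)
    columns = ["effective", "ineffective", "impulsive", "non_impulsive",
               "unclassified", "total"]
    if not recs:
        return pd.DataFrame(columns=[c for c in columns if c != "unclassified"])
    any_unclassified = any(
        r.caras is None or r.caras.effective is None or r.caras.impulsive is None
        for r in recs
    )

    def bucket(r: SubjectRecord) -> dict[str, int]:
        c = {"effective": 0, "ineffective": 0, "impulsive": 0,
             "non_impulsive": 0, "unclassified": 0, "total": 1}
        if r.caras is None or r.caras.effective is None or r.caras.impulsive is None:
            c["unclassified"] = 1
            return c
        c["effective" if r.caras.effective else "ineffective"] = 1
        c["impulsive" if r.caras.impulsive else "non_impulsive"] = 1
        return c

    groups = sorted({r.group for r in recs}, key=lambda g: (g != "adhd", g))
    index: list[str] = []
    data: list[dict[str, int]] = []
    for g in groups:
        for label, flag in (("completed", True), ("uncompleted", False)):
            sub = [r for r in recs if r.group == g and r.completed is flag]
            agg = {k: 0 for k in ("effective", "ineffective", "impulsive",
                                  "non_impulsive", "unclassified", "total")}
            for r in sub:
                for k, v in bucket(r).items():
                    agg[k] += v
            index.append(f"{g} {label}")
            data.append(agg)
        total = {k: data[-2][k] + data[-1][k] for k in data[-1]}
        index.append(f"{g} total")
        data.append(total)

    frame = pd.DataFrame(data, index=index)
    if not any_unclassified:
        frame = frame.drop(columns=["unclassified"])
    return frame


def comparisons_to_frame(
    comparisons: Iterable[GroupComparison], grouping: str
) -> pd.DataFrame:
    """Flatten comparisons into the analysis-report schema (one row/level)."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "grouping": grouping,
                "level": c.level,
                "n1": c.n1,
                "n2": c.n2,
                "mean1": c.mean1,
                "mean2": c.mean2,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "sig_raw": c.significant_raw,
                "sig_bonferroni": c.significant_bonferroni,
            }
        )
    return pd.DataFrame(rows)
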