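"""Group summaries and the two-tailed Mann-Whitney U test.

Every between-group claim in the analysis is backed by the same pair of
primitives: mean +/- standard error of the mean per group, and a
two-tailed Mann-Whitney U (Wilcoxon rank-sum) test per group pair. The
test is exact (full enumeration) for small tie-free samples and uses the
normal approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "TestResult", "mann_whitney_u", "group_summary", "compare_groups"]

EXACT_MAX_N = 20


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float  # standard error of the mean


@dataclass(frozen=True)
class TestResult:
    U: float
    p_two_tailed: float
    method: str  # exact | normal_approx
    tie_correction: bool


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test; ``U`` is the smaller of U1/U2.

    Exact enumeration when ``n1 + n2 <= 20`` and the pooled sample is
    tie-free; otherwise the normal approximation with continuity and tie
    corrections. Two identical constant groups give ``p = 1``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    ties = _has_ties(pooled)
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return TestResult(U=u, p_two_tailed=1.0, method="normal_approx", tie_correction=True)
    if len(pooled) <= EXACT_MAX_N and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    p = min(float(res.pvalue), 1.0)
    return TestResult(U=u, p_two_tailed=p, method=method, tie_correction=ties)


def group_summary(values: Iterable[float], label: str = "") -> GroupSummary:
    """Mean and SEM of a group; NA values must be removed beforehand.

    SEM is the sample standard deviation (ddof=1) over sqrt(n); a single
    value has SEM 0 by convention.
    """
    vals = np.asarray([v for v in values], dtype=float)
    if vals.size == 0:
        raise ValueError(f"group {label!r} is empty")
    if np.isnan(vals).any():
        raise ValueError(f"group {label!r} contains NA values; drop them first")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return GroupSummary(label=label, n=int(vals.size), mean=mean, se=se)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries for every group and a Mann-Whitney test per requested pair.

    Returns ``(summary_table, test_table)`` as TSV-ready DataFrames; the
    summary column is labelled ``sem`` explicitly.
    """
    for a, b in pairs:
        for lbl in (a, b):
            if lbl not in groups:
                raise KeyError(f"unknown group label {lbl!r} in pairs")
    summaries = [group_summary(vals, lbl) for lbl, vals in groups.items()]
    summary_df = pd.DataFrame(
        [{"group": s.label, "n": s.n, "mean": s.mean, "sem": s.se} for s in summaries]
    )
    rows = []
    for a, b in pairs:
        res = mann_whitney_u(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "U": res.U,
                "p_two_tailed": res.p_two_tailed,
                "method": res.method,
            }
        )
    test_df = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p_two_tailed", "method"]
    )
    return summary_df, test_df
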