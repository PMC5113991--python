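"""Replicate-level aggregation (mean +/- SEM) and two-group significance tests."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "summarize", "compare_groups", "ALPHA"]

#: significance level
ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard error of the mean (sample SD / sqrt(n)), replicate count."""

    mean: float
    sem: float
    n: int


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean +/- SEM of a replicate list; SEM is NaN (flagged) for n = 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return GroupSummary(mean=float(arr.mean()), sem=sem, n=int(arr.size))


def compare_groups(a: Sequence[float], b: Sequence[float],
                   welch: bool = False) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test: returns (t, p, significant at alpha = 0.05).

    Pooled-variance (classic Student) by default; ``welch=True`` drops the
    equal-variance assumption.  Degenerate input with zero variance in both
    groups returns t = 0, p = 1 when the means are equal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        t = math.copysign(math.inf, a.mean() - b.mean())
        return t, 0.0, True
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), bool(p < ALPHA)
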