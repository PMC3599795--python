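"""Nonparametric test wrappers with a fixed exact/asymptotic policy.

The Mann-Whitney U test is exact (full permutation distribution) when both
groups have at most 8 observations and the pooled sample is tie-free; it
falls back to the midrank normal approximation with tie correction
otherwise.  Two-sided throughout.  The asymptotic branch applies no
continuity correction, which makes the two-group Kruskal-Wallis statistic
exactly the square of the standardised U statistic and makes the two
p-values agree.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"; test name for kruskal


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns the U statistic of ``x`` and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise InsufficientDataError("Mann-Whitney requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied pooled sample: no evidence against exchangeability
        return TestResult(len(x) * len(y) / 2.0, 1.0, "degenerate")
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and tie_free:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(float(res.statistic), float(res.pvalue), "asymptotic")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups (midrank ties)."""
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal-Wallis requires >= 2 groups")
    stat, p = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return TestResult(float(stat), float(p), "kruskal-wallis")
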