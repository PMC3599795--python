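"""Assay quality control: allele-discrimination standard curve and
per-probe amplification efficiency from a serial dilution.

Discrimination: known allelic mixtures (artificial ratios of DNA from a
major-allele homozygote and a minor-allele homozygote, default two-fold
steps 8:1 down to 1:8) are measured and the observed well ratios regressed
on the expected ratios in log2-log2 space; slope ~ 1 and r^2 ~ 1 certify
that the assay measures ratio differences linearly over that range.

Efficiency: Ct of each probe across a two-fold serial dilution (200 ng
down to ~1.56 ng) is regressed on log10(input); the amplification base is
E = 10^(-1/slope), so a slope of -3.3219 is perfect doubling (100%
efficiency, percent efficiency = (E - 1) x 100).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

#: Default artificial mixture grid, two-fold steps from 8:1 to 1:8.
DEFAULT_MIXTURE_RATIOS = (8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125)

#: Default serial dilution: eight two-fold steps from 200 ng.
DEFAULT_DILUTION_NG = tuple(200.0 / 2**k for k in range(8))


@dataclass(frozen=True)
class DiscriminationCurve:
    """log2-log2 regression of observed on expected allelic ratios."""

    expected_ratios: tuple[float, ...]
    observed_ratios: tuple[float, ...]
    slope: float
    intercept: float  # log2 units
    r_squared: float

    def detectable(self, ratio: float) -> bool:
        """Whether ``ratio`` lies within the curve's validated range."""
        return min(self.expected_ratios) <= ratio <= max(self.expected_ratios)

    def passes(self, slope_range=(0.9, 1.1), min_r_squared=0.98) -> bool:
        return (
            slope_range[0] <= self.slope <= slope_range[1]
            and self.r_squared >= min_r_squared
        )


@dataclass(frozen=True)
class EfficiencyCurve:
    """Dilution-series regression of Ct on log10(input amount)."""

    input_amounts: tuple[float, ...]
    mean_cts: tuple[float, ...]
    slope: float
    efficiency: float  # amplification base E
    percent_efficiency: float
    r_squared: float


def fit_discrimination_curve(
    expected: Sequence[float], observed: Sequence[float]
) -> DiscriminationCurve:
    """Ordinary least squares of log2(observed) on log2(expected)."""
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(expected) != len(observed):
        raise ValueError("expected and observed ratios must match in length")
    if len(expected) < 3:
        raise InsufficientDataError(
            f"discrimination curve needs >= 3 points, got {len(expected)}"
        )
    if np.any(expected <= 0) or np.any(observed <= 0):
        raise ValueError("ratios must be positive")
    fit = sps.linregress(np.log2(expected), np.log2(observed))
    return DiscriminationCurve(
        tuple(expected), tuple(observed),
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2),
    )


def fit_efficiency_curve(
    amounts: Sequence[float], cts: Sequence[float]
) -> EfficiencyCurve:
    """Amplification efficiency from a serial dilution.

    ``amounts`` and ``cts`` are matched per-well values; replicate wells
    of the same input amount are averaged before the regression.  A
    non-monotone mean-Ct profile is logged as a warning but still fitted.
    """
    amounts = np.asarray(amounts, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if len(amounts) != len(cts):
        raise ValueError("amounts and cts must match in length")
    if np.any(amounts <= 0):
        raise ValueError("input amounts must be positive")
    levels = np.unique(amounts)[::-1]  # strictly decreasing
    if len(levels) < 3:
        raise InsufficientDataError(
            f"efficiency curve needs >= 3 dilution points, got {len(levels)}"
        )
    mean_cts = np.array([cts[amounts == a].mean() for a in levels])
    if np.any(np.diff(mean_cts) < 0):
        logger.warning(
            "mean Cts are not monotone increasing with dilution; "
            "fitting anyway"
        )
    fit = sps.linregress(np.log10(levels), mean_cts)
    efficiency = float(10.0 ** (-1.0 / fit.slope))
    return EfficiencyCurve(
        tuple(levels), tuple(mean_cts),
        float(fit.slope), efficiency, (efficiency - 1.0) * 100.0,
        float(fit.rvalue**2),
    )
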