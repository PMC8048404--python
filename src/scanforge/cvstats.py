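"""Measurement-precision statistics: coefficients of variation and the
Feltz-Miller equality test.

The coefficient of variation c_v = sigma/mu is a scale-free precision
measure, suited to comparing measurement protocols (e.g. calliper
measurements on a physical specimen versus distances taken on its 3D model)
whose means differ.  Equality of CVs across k groups is tested with the
asymptotic chi-square test of Feltz & Miller (1996): with m_i = n_i - 1,
c_i = s_i / xbar_i and the weighted pooled CV

    c = sum(m_i c_i) / sum(m_i),

the statistic

    D = sum(m_i (c_i - c)^2) / (c^2 (0.5 + c^2))

is asymptotically chi-square with k - 1 degrees of freedom under equality.
The test operates on group summaries (n, mean, sd); a convenience wrapper
accepts raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UndefinedCVError


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: size, mean and (ddof=1) sd."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError("group size must be >= 2")
        if self.sd < 0:
            raise InvalidInputError("sd must be non-negative")

    @classmethod
    def from_samples(cls, samples: Sequence[float], label: str = "") -> "GroupSummary":
        x = np.asarray(samples, dtype=np.float64)
        if x.size < 2:
            raise InvalidInputError("need at least 2 samples")
        return cls(n=int(x.size), mean=float(x.mean()),
                   sd=float(x.std(ddof=1)), label=label)


def cv(summary: GroupSummary) -> float:
    """Coefficient of variation sigma/mu; undefined for zero mean."""
    if summary.mean == 0:
        raise UndefinedCVError(
            f"CV undefined for zero-mean group {summary.label!r}"
        )
    return summary.sd / summary.mean


def cv_rounded(summary: GroupSummary, decimals: int = 3) -> float:
    """CV rounded for reporting (3 decimals by convention)."""
    return round(cv(summary), decimals)


@dataclass(frozen=True)
class FeltzMillerResult:
    statistic: float
    df: int
    p_value: float


def feltz_miller_test(groups: Sequence[GroupSummary]) -> FeltzMillerResult:
    """Asymptotic test for equality of CVs across k populations.

    Returns the chi-square statistic (often printed as D_AD), its degrees of
    freedom k - 1, and the upper-tail p-value.  The statistic is invariant
    to group relabelling and to rescaling any group's mean and sd by the
    same positive constant.
    """
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    m = np.array([g.n - 1 for g in groups], dtype=np.float64)
    c_i = np.array([cv(g) for g in groups])
    pooled = float((m * c_i).sum() / m.sum())
    if pooled == 0:
        # all groups have zero spread: trivially equal CVs
        return FeltzMillerResult(0.0, len(groups) - 1, 1.0)
    statistic = float((m * (c_i - pooled) ** 2).sum()
                      / (pooled**2 * (0.5 + pooled**2)))
    df = len(groups) - 1
    p = float(stats.chi2.sf(statistic, df))
    return FeltzMillerResult(statistic, df, p)


def feltz_miller_test_samples(
    samples: Sequence[Sequence[float]],
) -> FeltzMillerResult:
    """Feltz-Miller test from raw samples (summaries computed first)."""
    return feltz_miller_test([GroupSummary.from_samples(s) for s in samples])


def loglog_slope(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """OLS slope of log10(y) on log10(x) with a (1-alpha) confidence interval.

    Utility for allometric scaling analyses (e.g. surface area against
    volume).  Requires strictly positive data.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidInputError("log-log regression requires positive data")
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need >= 3 paired observations")
    res = stats.linregress(np.log10(x), np.log10(y))
    t = stats.t.ppf(1 - alpha / 2, x.size - 2)
    return float(res.slope), (
        float(res.slope - t * res.stderr),
        float(res.slope + t * res.stderr),
    )
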