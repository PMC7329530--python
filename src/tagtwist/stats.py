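"""Agreement and group-comparison statistics.

Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 sample SD of the
paired differences, the literal 1.96 rather than a t quantile), Spearman rank
correlation, the Kruskal-Wallis H test, and mean +/- SD group summaries —
the statistics used to compare the two tracking engines and the study groups.
Rank-based tests use mid-ranks on ties and the standard large-sample
approximations (t for Spearman, chi-squared for Kruskal-Wallis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "BlandAltmanResult",
    "GroupComparison",
    "bland_altman",
    "spearman_rho",
    "kruskal_wallis",
    "group_summary",
    "compare_groups",
    "ALPHA",
]

ALPHA = 0.05


class SampleSizeError(ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(ValueError):
    """Statistic undefined on this input (constant or all-tied data)."""


@dataclass
class BlandAltmanResult:
    """Paired-method agreement: bias and 95% limits of agreement."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    percent_within_loa: float
    n: int

    @property
    def significant_bias(self) -> bool:
        """Whether zero lies outside bias +/- 1.96 SE (alpha = 0.05)."""
        if self.sd_diff == 0:
            return self.bias != 0
        se = self.sd_diff / np.sqrt(self.n)
        return abs(self.bias) > 1.96 * se


@dataclass
class GroupComparison:
    """Per-group mean +/- SD with a Kruskal-Wallis omnibus test."""

    labels: list[str]
    sizes: list[int]
    means: list[float]
    sds: list[float]
    H: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Differences d = x - y; bias = mean(d); limits = bias +/- 1.96 x sample SD
    (n-1 denominator). ``percent_within_loa`` is the share of differences
    strictly inside the limits (100 when the differences have zero variance,
    with a warning, since the limits collapse onto the bias).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise SampleSizeError("Bland-Altman requires n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    if sd == 0:
        warnings.warn("zero-variance differences: limits of agreement collapse to the bias")
        pct = 100.0
    else:
        pct = 100.0 * float(np.mean((d > lo) & (d < hi)))
    return BlandAltmanResult(bias=bias, loa_lower=lo, loa_upper=hi, sd_diff=sd,
                             percent_within_loa=pct, n=int(x.size))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's rank correlation (mid-ranks on ties) with the large-sample
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise SampleSizeError("spearman_rho requires equal-length 1-D arrays, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("correlation undefined for a constant input vector")
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H on pooled mid-ranks with the standard tie correction;
    p from the chi-squared approximation with k-1 degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise SampleSizeError("kruskal_wallis requires >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise SampleSizeError("kruskal_wallis requires total n >= 3")
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all pooled values identical: tie correction degenerate")
    H, p = _sps.kruskal(*groups)
    return float(H), float(p)


def group_summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise SampleSizeError("group_summary requires n >= 2")
    return float(np.mean(v)), float(np.std(v, ddof=1))


def compare_groups(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Summaries plus the Kruskal-Wallis omnibus test over labelled groups."""
    labels = list(groups)
    vals = [np.asarray(groups[k], dtype=float) for k in labels]
    H, p = kruskal_wallis(vals)
    means, sds = zip(*(group_summary(v) for v in vals))
    return GroupComparison(labels=labels, sizes=[int(v.size) for v in vals],
                           means=list(means), sds=list(sds), H=H, p_value=p)
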