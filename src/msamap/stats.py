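"""Region-level evaluation statistics.

Per-region mean-absolute time courses of the projected maps, an empirical
quantile threshold for significance, the selectivity summary (fraction of
significant time points landing in the target region, and their median
timing), an exact one-tailed Wilcoxon signed-rank test, and the
Agresti-Coull adjusted-Wald margin of error for a binomial success count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm, rankdata

from .projection import CorticalMap
from .synthetic import REGIONS

__all__ = [
    "RegionTimeSeries",
    "SelectivitySummary",
    "MOEResult",
    "region_timecourse",
    "detect_significant",
    "selectivity_summary",
    "wilcoxon_signed_rank_one_tailed",
    "adjusted_wald_moe",
]


@dataclass(frozen=True)
class RegionTimeSeries:
    """Region x time mean-absolute values, optionally with significance flags."""

    regions: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray                 # (R, T), >= 0
    threshold: float | None = None
    significant: np.ndarray | None = None  # (R, T) bool

    def region_row(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise ValueError(f"unknown region {region!r}") from None


@dataclass(frozen=True)
class SelectivitySummary:
    """Where and when the significant time points fall."""

    target_region: str
    counts: dict[str, int]          # significant points per region
    pct_significant: float | None   # % of all significant points in target
    median_timing: float | None     # s; None when the target has no points

    @property
    def total_significant(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MOEResult:
    """Adjusted-Wald (Agresti-Coull) margin of error for x successes of n."""

    x: int
    n: int
    Z: float
    p_adj: float          # p' = (x+2)/(n+4)
    V_adj: float          # V' = p'(1-p')/(n+4)
    moe: float            # Z * sqrt(V')
    effectiveness: float  # (1-moe) * (x/n)


def region_timecourse(cmap: CorticalMap,
                      regions: tuple[str, ...] | None = None) -> RegionTimeSeries:
    """Mean absolute vertex value per region at each time point.

    ``regions`` defaults to the labels present on the mesh (canonical order
    first); a requested region with no vertices is an error.
    """
    labels = cmap.mesh.region_label
    if regions is None:
        present = set(labels)
        regions = tuple(r for r in REGIONS if r in present)
        regions += tuple(sorted(present - set(regions)))
    empty = [r for r in regions if not np.any(labels == r)]
    if empty:
        raise ValueError(f"empty region(s): {', '.join(empty)}")
    absvals = np.abs(cmap.values)
    values = np.stack([absvals[labels == r].mean(axis=0) for r in regions])
    return RegionTimeSeries(regions=tuple(regions), times=cmap.times.copy(),
                            values=values)


def detect_significant(rts: RegionTimeSeries, q: float = 0.95) -> RegionTimeSeries:
    """Flag region/time points exceeding the pooled empirical q-quantile.

    The distribution pools all region x time values of the run; the
    threshold uses the linear-interpolation quantile convention and flags
    are strict (value > threshold), so identical values are never flagged.
    """
    if not 0 < q < 1:
        raise ValueError("need 0 < q < 1")
    pooled = rts.values.ravel()
    if pooled.size < 20:
        warnings.warn(
            f"only {pooled.size} pooled values; the q={q:g} quantile "
            "threshold is unstable", stacklevel=2,
        )
    threshold = float(np.quantile(pooled, q))
    return replace(rts, threshold=threshold, significant=rts.values > threshold)


def selectivity_summary(rts: RegionTimeSeries, target: str) -> SelectivitySummary:
    """Fraction and timing of significant points in the target region.

    With zero significant points overall the percentage is undefined and
    reported as None, not 0.
    """
    row = rts.region_row(target)
    if rts.significant is None:
        raise ValueError("run detect_significant first")
    counts = {r: int(rts.significant[i].sum()) for i, r in enumerate(rts.regions)}
    total = sum(counts.values())
    pct = 100.0 * counts[target] / total if total > 0 else None
    target_times = rts.times[rts.significant[row]]
    median_timing = float(np.median(target_times)) if target_times.size else None
    return SelectivitySummary(target_region=target, counts=counts,
                              pct_significant=pct, median_timing=median_timing)


_EXACT_LIMIT = 25


def wilcoxon_signed_rank_one_tailed(a, b) -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank test of the alternative a > b.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    W is the sum of ranks of positive differences. For up to 25 effective
    pairs the p-value is exact (full null distribution of W over all sign
    assignments, with the observed ranks); beyond that a continuity-corrected
    normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    n = d.size
    if n <= _EXACT_LIMIT:
        # mid-ranks are multiples of 1/2: work in doubled integer units and
        # convolve the null distribution of W one rank at a time
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts += shifted
        w2 = int(np.rint(2 * w))
        p = counts[w2:].sum() / 2.0**n
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(float((ranks**2).sum()) / 4.0)
        p = float(norm.sf((w - mean - 0.5) / sd))
    return w, float(min(p, 1.0))


def adjusted_wald_moe(x: int, n: int, Z: float = 1.96) -> MOEResult:
    """Agresti-Coull adjusted-Wald margin of error and effectiveness bound.

    Adds two successes and two failures before forming the Wald interval:
    p' = (x+2)/(n+4), V' = p'(1-p')/(n+4), MOE = Z*sqrt(V'); the
    effectiveness lower bound is (1-MOE)*(x/n). Reliable at small n and
    extreme proportions.
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError("need 0 <= x <= n and n >= 1")
    if Z < 0:
        raise ValueError("Z must be >= 0")
    p_adj = (x + 2) / (n + 4)
    v_adj = p_adj * (1 - p_adj) / (n + 4)
    moe = Z * np.sqrt(v_adj)
    return MOEResult(x=int(x), n=int(n), Z=float(Z), p_adj=float(p_adj),
                     V_adj=float(v_adj), moe=float(moe),
                     effectiveness=float((1 - moe) * (x / n)))
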