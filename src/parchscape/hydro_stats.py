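"""Distributional statistics of PARCH values.

Gaussian kernel density estimates with Silverman's rule-of-thumb
bandwidth, prominence-filtered mode finding, two-sided Mann-Whitney U
group comparisons with the conventional significance-star labels, and
five-number violin summaries.  The estimator and test choices are
package conventions: violin-plot group comparisons in this field are
conventionally nonparametric, and the rank-sum test makes no
distributional assumption about the PV samples.

Quantiles use linear interpolation between order statistics (numpy's
default), so summaries are bit-reproducible across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import InputError

__all__ = [
    "DensityEstimate",
    "GroupComparison",
    "ViolinSummary",
    "silverman_bandwidth",
    "kde",
    "find_modes",
    "compare_groups",
    "stars_for",
    "violin_summary",
]

#: significance-star thresholds, strongest first
STAR_THRESHOLDS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pv": self.grid, "density": self.density})


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    stars: str
    n1: int
    n2: int
    median_shift: float
    method: str


@dataclass
class ViolinSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    n: int


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise InputError("zero-variance sample: rule-based bandwidth undefined")
    return float(0.9 * spread * n ** (-0.2))


def kde(values: np.ndarray, bandwidth: float | str = "silverman") -> DensityEstimate:
    """Gaussian-kernel density on a grid spanning [min-3h, max+3h], step <= h/5."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise InputError("kde requires at least 2 values")
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise InputError(f"unknown bandwidth rule {bandwidth!r}")
        h = silverman_bandwidth(values)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise InputError("bandwidth must be positive")
    lo, hi = values.min() - 3 * h, values.max() + 3 * h
    n_pts = int(np.ceil((hi - lo) / (h / 5))) + 1
    grid = np.linspace(lo, hi, n_pts)
    sd = values.std(ddof=1)
    if sd == 0:
        # fixed bandwidth on a degenerate sample: evaluate the kernel sum directly
        density = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2).sum(axis=1)
        density /= values.size * h * np.sqrt(2 * np.pi)
    else:
        estimator = stats.gaussian_kde(values, bw_method=h / sd)
        density = estimator(grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=h)


def find_modes(d: DensityEstimate, min_prominence: float = 0.05) -> list[float]:
    """Locations of density maxima with prominence >= fraction of the peak height.

    Interior local maxima come from peak detection; a strictly higher
    endpoint also counts as a mode (a one-sided peak).  Locations are
    returned in ascending order.
    """
    density = d.density
    if density.size == 0:
        return []
    if density.size == 1:
        return [float(d.grid[0])]
    threshold = min_prominence * float(density.max())
    peaks, _ = signal.find_peaks(density, prominence=threshold)
    modes = [float(d.grid[i]) for i in peaks]
    # endpoints cannot be found by find_peaks; treat a falling edge as a mode
    if density[0] > density[1] and density[0] >= threshold:
        modes.insert(0, float(d.grid[0]))
    if density[-1] > density[-2] and density[-1] >= threshold:
        modes.append(float(d.grid[-1]))
    return sorted(modes)


def stars_for(p_value: float) -> str:
    for threshold, label in STAR_THRESHOLDS:
        if p_value < threshold:
            return label
    return "ns"


def compare_groups(x: np.ndarray, y: np.ndarray) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two PV samples.

    Exact enumeration of the U null distribution for small tie-free
    samples (both n <= 20); the normal approximation with tie correction
    and continuity correction otherwise.  The U statistic reported is
    the x-side statistic (number of (x, y) pairs with x > y, counting
    ties as half).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise InputError("both samples need at least 2 values")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(res.pvalue)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=p,
        stars=stars_for(p),
        n1=int(x.size),
        n2=int(y.size),
        median_shift=float(np.median(x) - np.median(y)),
        method=method,
    )


def violin_summary(values: np.ndarray) -> ViolinSummary:
    """Five-number summary (linear-interpolation quantiles) plus n."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise InputError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return ViolinSummary(
        min=float(values.min()), q1=float(q1), median=float(med),
        q3=float(q3), max=float(values.max()), n=int(values.size),
    )
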