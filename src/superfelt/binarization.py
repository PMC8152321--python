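"""ln(IC50) binarization by resampling, pooled KDE, and threshold extraction.

Continuous drug-response summaries are turned into sensitive/resistant
labels the way cell-line screens are commonly dichotomized: each cell
line's ln(IC50) is smeared into ``draws_per_sample`` normal draws (sd =
``interval``, a stand-in for per-line measurement uncertainty), the pooled
draws are density-estimated with a fixed-bandwidth Gaussian kernel, and
the cutoff is placed at the density minimum between the two dominant
modes of the (assumed bimodal) population. Samples below the cutoff —
responding at low concentration — are sensitive. When the pooled density
is unimodal the cutoff falls back to pooled mean minus one pooled sd, so
only the low-ln(IC50) tail is called sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import ConfigurationError, DegenerateDensityError
from .omics_data import IC50Table, LabelVector

# a 95% CI covers +-1.96 sd, i.e. width / 3.92 per sd
_CI95_WIDTH_PER_SD = 2 * 1.959963984540054


@dataclass
class BinarizationConfig:
    """``interval`` is read as the resampling sd directly; set
    ``interval_is_ci95`` to treat it as a full 95% CI width instead."""

    draws_per_sample: int = 100
    interval: float = 0.5
    kde_bandwidth: float = 0.5
    grid_points: int = 512
    seed: int = 0
    interval_is_ci95: bool = False

    def __post_init__(self) -> None:
        for name in ("draws_per_sample", "interval", "kde_bandwidth", "grid_points"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def sigma(self) -> float:
        return self.interval / _CI95_WIDTH_PER_SD if self.interval_is_ci95 else self.interval


@dataclass
class BinarizationResult:
    threshold: float
    labels: LabelVector  # 1 = sensitive (ln_ic50 < threshold)
    grid: np.ndarray  # (grid_points,) evaluation points
    density: np.ndarray  # KDE values on the grid
    modes: np.ndarray = field(default_factory=lambda: np.empty(0))
    minima: np.ndarray = field(default_factory=lambda: np.empty(0))
    unimodal_fallback: bool = False


def resample(ic50: IC50Table, cfg: BinarizationConfig) -> np.ndarray:
    """Draw ``draws_per_sample`` values per cell line from
    Normal(ln_ic50_i, sigma); pooled length is draws * n."""
    rng = np.random.default_rng(cfg.seed)
    centers = np.repeat(ic50.ln_ic50, cfg.draws_per_sample)
    return rng.normal(centers, cfg.sigma)


def kde_density(pool: np.ndarray, cfg: BinarizationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bandwidth Gaussian KDE on an even grid spanning the pool
    plus three bandwidths each side."""
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ConfigurationError("empty pool")
    bw = cfg.kde_bandwidth
    grid = np.linspace(pool.min() - 3 * bw, pool.max() + 3 * bw, cfg.grid_points)
    sd = pool.std(ddof=1) if pool.size > 1 else 0.0
    if sd == 0.0:
        # single point (or zero spread): the density is one Gaussian bump
        density = np.exp(-0.5 * ((grid - pool[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    else:
        # gaussian_kde's factor multiplies the data sd; rescale for absolute bw
        density = gaussian_kde(pool, bw_method=bw / sd)(grid)
    return grid, density


def find_threshold(
    grid: np.ndarray, density: np.ndarray, pool: np.ndarray | None = None
) -> float:
    """Cutoff between the two dominant density modes.

    With >= 2 local maxima: the grid point of minimum density strictly
    between the two highest modes. Unimodal: mean - 1 sd (of ``pool``
    when provided, else of the density itself).
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.ptp(density) <= 1e-15:
        raise DegenerateDensityError("flat density; no threshold")
    peaks, _ = find_peaks(density)
    if peaks.size >= 2:
        top2 = peaks[np.argsort(density[peaks])[::-1][:2]]
        lo, hi = int(top2.min()), int(top2.max())
        inner = slice(lo + 1, hi)
        if inner.stop > inner.start:
            j = lo + 1 + int(np.argmin(density[inner]))
            return float(grid[j])
    if pool is not None:
        mean, sd = float(np.mean(pool)), float(np.std(pool, ddof=1))
    else:
        w = density / density.sum()
        mean = float((grid * w).sum())
        sd = float(np.sqrt(((grid - mean) ** 2 * w).sum()))
    return mean - sd


def binarize(ic50: IC50Table, cfg: BinarizationConfig | None = None) -> BinarizationResult:
    """Resample, pool, density-estimate, and threshold an ln(IC50) table."""
    cfg = cfg or BinarizationConfig()
    if np.ptp(ic50.ln_ic50) == 0.0:
        raise DegenerateDensityError("all ln(IC50) values identical; no threshold exists")
    pool = resample(ic50, cfg)
    grid, density = kde_density(pool, cfg)
    peaks, _ = find_peaks(density)
    threshold = find_threshold(grid, density, pool)
    labels = LabelVector(list(ic50.sample_ids), (ic50.ln_ic50 < threshold).astype(int))
    return BinarizationResult(
        threshold=threshold,
        labels=labels,
        grid=grid,
        density=density,
        modes=grid[peaks],
        minima=grid[find_peaks(-density)[0]],
        unimodal_fallback=peaks.size < 2,
    )
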