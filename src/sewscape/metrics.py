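"""Spatial early-warning indicators computed on a single snapshot.

Four indicators of reduced ecosystem resilience, each computed from one
gridded snapshot: spatial variance, spatial skewness, Moran's I spatial
autocorrelation, and the spectral density ratio (SDR).  As a system
approaches a fold bifurcation, local recovery slows down and spatial
pattern coarsens: variance and Moran's I rise while the SDR (power at
low relative to high spatial frequencies, see below) falls.

All moments are population moments (divide by N), so that on binary maps
the exact Bernoulli identities var = m(1-m) and skew = (1-2m)/sqrt(m(1-m))
hold to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau

from .grid import Grid, SnapshotSeries

__all__ = [
    "SEWSResult",
    "UndefinedMetricError",
    "spatial_variance",
    "spatial_skewness",
    "morans_i",
    "spectral_density_ratio",
    "sews_summary",
    "gradient_trend",
    "METRICS",
]


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined on this grid (e.g. zero variance)."""


def mean_cover(grid: Grid) -> float:
    """Spatial mean of the snapshot (fractional cover for binary grids)."""
    return grid.mean()


def spatial_variance(grid: Grid) -> float:
    """Population variance over non-missing cells."""
    v = grid.unmasked_values()
    if v.size < 2:
        raise ValueError("need at least 2 valid cells")
    return float(np.var(v))


def spatial_skewness(grid: Grid) -> float:
    """Population third standardized moment over non-missing cells."""
    v = grid.unmasked_values().astype(float)
    if v.size < 2:
        raise ValueError("need at least 2 valid cells")
    var = np.var(v)
    if var == 0:
        raise UndefinedMetricError("skewness undefined on a zero-variance grid")
    z = v - v.mean()
    return float(np.mean(z**3) / var**1.5)


def morans_i(grid: Grid, neighbourhood: str = "rook", periodic: bool = False) -> float:
    """Global Moran's I with binary lag-1 neighbour weights.

    I = (N/W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the deviation from
    the spatial mean, w_ij = 1 for lag-1 neighbours (rook: 4-neighbour,
    queen: 8-neighbour), W the total weight.  Pairs touching missing cells
    are excluded.  Under spatial randomness E[I] = -1/(N-1).
    """
    if neighbourhood not in ("rook", "queen"):
        raise ValueError("neighbourhood must be 'rook' or 'queen'")
    valid = ~grid.mask
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    v = grid.values.astype(float)
    mean = v[valid].mean()
    z = np.where(valid, v - mean, 0.0)
    denom = float((z[valid] ** 2).sum())
    if denom == 0:
        raise UndefinedMetricError("Moran's I undefined on a zero-variance grid")

    offsets = [(0, 1), (1, 0)]
    if neighbourhood == "queen":
        offsets += [(1, 1), (1, -1)]

    num = 0.0
    w = 0.0
    for dr, dc in offsets:
        if periodic:
            z2 = np.roll(np.roll(z, -dr, axis=0), -dc, axis=1)
            v2 = np.roll(np.roll(valid, -dr, axis=0), -dc, axis=1)
            pair_valid = valid & v2
            num += float((z * z2)[pair_valid].sum())
            w += float(pair_valid.sum())
        else:
            nrows, ncols = z.shape
            rs_a, rs_b = slice(0, nrows - dr), slice(dr, nrows)
            if dc >= 0:  # dc may be -1 for the queen anti-diagonal
                cs_a, cs_b = slice(0, ncols - dc), slice(dc, ncols)
            else:
                cs_a, cs_b = slice(-dc, ncols), slice(0, ncols + dc)
            za, zb = z[rs_a, cs_a], z[rs_b, cs_b]
            pair_valid = valid[rs_a, cs_a] & valid[rs_b, cs_b]
            num += float((za * zb)[pair_valid].sum())
            w += float(pair_valid.sum())
    if w == 0:
        raise ValueError("no valid neighbour pairs")
    # offsets count each unordered pair once; the symmetric double counting
    # cancels between numerator and W
    return float((n / w) * (num / denom))


def spectral_density_ratio(grid: Grid, fill_masked: bool = False) -> float:
    """Ratio of low- to high-frequency spectral power of the snapshot.

    The mean is removed, the 2-D periodogram |FFT|^2 computed, and
    frequencies binned by their integer radial wavenumber relative to
    f_max = min(nrows, ncols) // 2.  SDR is the mean periodogram value
    over radii in (0, 0.2 f_max] divided by the mean over radii
    >= 0.8 f_max.  Mean (not summed) band power makes white noise come
    out at ~1 independent of grid size.  Coarse, large-scale patterns give
    SDR >> 1; fine, alternating ones give SDR ~ 0.

    Missing cells are rejected unless ``fill_masked`` is set, in which
    case they are filled with the grid mean (flagged approximation).
    """
    if grid.mask.any():
        if not fill_masked:
            raise ValueError(
                "SDR needs a complete grid; pass fill_masked=True to fill "
                "missing cells with the mean"
            )
        v = grid.values.astype(float).copy()
        v[grid.mask] = grid.mean()
    else:
        v = grid.values.astype(float)
    nr, nc = v.shape
    if min(nr, nc) < 8:
        raise ValueError("grid must be at least 8x8 for a stable periodogram")
    z = v - v.mean()
    if np.all(z == 0):
        raise UndefinedMetricError("SDR undefined on a zero-variance grid")
    power = np.abs(np.fft.fft2(z)) ** 2
    ky = np.fft.fftfreq(nr) * nr
    kx = np.fft.fftfreq(nc) * nc
    radius = np.hypot(*np.meshgrid(ky, kx, indexing="ij"))
    f_max = min(nr, nc) // 2
    low = (radius > 0) & (radius <= 0.2 * f_max)
    high = radius >= 0.8 * f_max
    if not high.any():
        raise ValueError("empty high-frequency band (grid too small)")
    high_mean = power[high].mean()
    low_mean = power[low].mean() if low.any() else 0.0
    if high_mean == 0:
        return 0.0 if low_mean == 0 else np.inf
    return float(low_mean / high_mean)


#: metric name -> callable; the names are the public vocabulary used by
#: sews_summary, null models and the CLI.
METRICS = {
    "mean_cover": mean_cover,
    "spatial_variance": spatial_variance,
    "spatial_skewness": spatial_skewness,
    "morans_i": morans_i,
    "sdr": spectral_density_ratio,
}

#: metrics that do not depend on the spatial arrangement of cells
PERMUTATION_INVARIANT = frozenset(
    {"mean_cover", "spatial_variance", "spatial_skewness"}
)


@dataclass
class SEWSResult:
    """Per-snapshot indicator record.

    Undefined metrics are reported as ``None`` with the reason in
    ``missing`` rather than fabricated.
    """

    mean_cover: float
    spatial_variance: float | None = None
    spatial_skewness: float | None = None
    morans_i: float | None = None
    sdr: float | None = None
    missing: dict = field(default_factory=dict)
    envelopes: dict = field(default_factory=dict)

    def get(self, metric: str):
        return getattr(self, metric)


def sews_summary(grid: Grid, periodic: bool = False,
                 fill_masked: bool = False) -> SEWSResult:
    """All four indicators (plus mean cover) on one snapshot."""
    res = SEWSResult(mean_cover=mean_cover(grid))
    for name in ("spatial_variance", "spatial_skewness", "morans_i", "sdr"):
        try:
            if name == "morans_i":
                value = morans_i(grid, periodic=periodic)
            elif name == "sdr":
                value = spectral_density_ratio(grid, fill_masked=fill_masked)
            else:
                value = METRICS[name](grid)
            setattr(res, name, value)
        except (UndefinedMetricError, ValueError) as exc:
            res.missing[name] = str(exc)
    return res


def gradient_trend(series: SnapshotSeries, metric: str, periodic: bool = False):
    """Kendall rank correlation of an indicator against the gradient.

    Returns ``(tau, p_value, direction)`` with direction in
    {"increasing", "decreasing", "flat"}.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 snapshots for a trend")
    xs, ys = [], []
    n_missing = 0
    for g_value, grid in series:
        summary = sews_summary(grid, periodic=periodic)
        val = summary.get(metric)
        if val is None:
            n_missing += 1
            continue
        xs.append(g_value)
        ys.append(val)
    if n_missing > len(series) / 2:
        raise ValueError(f"metric {metric!r} missing in more than half the snapshots")
    tau, p = kendalltau(xs, ys)
    if np.isnan(tau) or tau == 0:
        direction = "flat"
        tau = 0.0 if np.isnan(tau) else tau
    else:
        direction = "increasing" if tau > 0 else "decreasing"
    return float(tau), float(p), direction
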