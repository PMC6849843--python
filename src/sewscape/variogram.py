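"""Variogram-based spatial structure analysis.

The empirical semivariogram gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) over
cell pairs at separation h summarizes how similarity decays with
distance.  Fitting a spherical or exponential model decomposes the
variance into a *nugget* (spatially unstructured noise), a *partial sill*
(spatially structured variance) and a *correlation range* — the distance
beyond which cells are effectively uncorrelated, interpretable as the
mean patch size of the landscape.  Along a stress gradient approaching a
regime shift, sill, correlation range and the relative structural
variance (RSV = 100 * psill / (psill + nugget)) all rise, making the
fitted parameters early-warning indicators in their own right.  The
correlation range also sets the optimal observation resolution: by the
sampling theorem a pattern of typical length scale D_c needs cells no
coarser than D_c / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .grid import Grid, SnapshotSeries

__all__ = [
    "EmpiricalVariogram",
    "VariogramFit",
    "empirical_variogram",
    "cross_variogram",
    "fit_variogram",
    "relative_structural_variance",
    "optimal_resolution",
    "variogram_sews",
]


@dataclass
class EmpiricalVariogram:
    """Binned (cross-)semivariogram: lag centres (m), semivariance, pair counts."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    direction: tuple[float, float] | None = None  # (azimuth deg, tolerance deg)
    cross: bool = False

    def nonempty(self) -> "EmpiricalVariogram":
        keep = self.counts > 0
        return EmpiricalVariogram(
            self.lags[keep], self.gamma[keep], self.counts[keep],
            self.direction, self.cross,
        )


@dataclass
class VariogramFit:
    """Fitted variogram model parameters.

    ``range_param`` is the model parameter ``a``; ``correlation_range`` is
    the practical range: ``a`` for the spherical model (exact) and ``3a``
    for the exponential (the lag at 95% of the sill).
    """

    family: str
    nugget: float
    partial_sill: float
    range_param: float
    converged: bool
    residual_ss: float
    structure_pvalue: float = 0.0

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def correlation_range(self) -> float:
        return self.range_param if self.family == "spherical" else 3.0 * self.range_param

    @property
    def rsv(self) -> float:
        return relative_structural_variance(self)


def _offsets(max_lag_cells: float, direction=None):
    """Half-plane lattice offsets with distance <= max_lag (each pair once)."""
    m = int(np.ceil(max_lag_cells))
    offs = []
    for dr in range(0, m + 1):
        for dc in range(-m, m + 1):
            if dr == 0 and dc <= 0:
                continue  # half-plane: dr>0, or dr==0 and dc>0
            dist = np.hypot(dr, dc)
            if dist > max_lag_cells:
                continue
            if direction is not None:
                az, tol = direction
                # azimuth measured clockwise from "north" (decreasing row)
                ang = np.degrees(np.arctan2(dc, dr)) % 180.0
                diff = min(abs(ang - az % 180.0), 180.0 - abs(ang - az % 180.0))
                if diff > tol:
                    continue
            offs.append((dr, dc, dist))
    return offs


def _pair_sums(a: np.ndarray, b: np.ndarray, valid: np.ndarray,
               dr: int, dc: int, keep: np.ndarray | None):
    """Sum of (da * db) products and pair count at one lattice offset."""
    nr, nc = a.shape
    rs0, rs1 = slice(0, nr - dr), slice(dr, nr)
    if dc >= 0:
        cs0, cs1 = slice(0, nc - dc), slice(dc, nc)
    else:
        cs0, cs1 = slice(-dc, nc), slice(0, nc + dc)
    ok = valid[rs0, cs0] & valid[rs1, cs1]
    if keep is not None:
        ok = ok & keep[rs0, cs0]
    da = a[rs0, cs0] - a[rs1, cs1]
    db = b[rs0, cs0] - b[rs1, cs1]
    return float((da * db)[ok].sum()), int(ok.sum())


def _variogram(
    grid_a: Grid,
    grid_b: Grid,
    lag_width: float | None,
    max_lag: float | None,
    direction,
    max_pairs: int | None,
    seed: int,
    cross: bool,
) -> EmpiricalVariogram:
    if grid_a.shape != grid_b.shape:
        raise ValueError("grids must be congruent")
    cell = grid_a.cell_size
    nr, nc = grid_a.shape
    if max_lag is None:
        max_lag = min(nr, nc) * cell / 3.0
    half_diag = 0.5 * np.hypot(nr * cell, nc * cell)
    if max_lag > half_diag:
        warnings.warn(
            f"max_lag {max_lag:.1f} m exceeds half the grid diagonal "
            f"({half_diag:.1f} m); large-lag bins will be unreliable",
            stacklevel=2,
        )
    if lag_width is None:
        lag_width = cell
    valid = ~(grid_a.mask | grid_b.mask)
    if valid.sum() < 2:
        raise ValueError("need at least 2 jointly valid cells")
    a = np.where(valid, grid_a.values.astype(float), 0.0)
    b = np.where(valid, grid_b.values.astype(float), 0.0)

    offs = [
        (dr, dc, dist)
        for dr, dc, dist in _offsets(max_lag / cell, direction)
        if dr < nr and abs(dc) < nc
    ]
    n_bins = int(np.ceil(max_lag / lag_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    dist_sums = np.zeros(n_bins)

    keep = None
    if max_pairs is not None:
        total = sum(
            max(0, (nr - dr)) * (nc - abs(dc)) for dr, dc, _ in offs
        )
        if total > max_pairs:
            frac = max_pairs / total
            rng = np.random.default_rng(seed)
            keep = rng.random((nr, nc)) < frac

    for dr, dc, dist in offs:
        h = dist * cell
        bin_idx = min(int(h / lag_width - 1e-9), n_bins - 1)
        s, n = _pair_sums(a, b, valid, dr, dc, keep)
        sums[bin_idx] += s
        counts[bin_idx] += n
        dist_sums[bin_idx] += n * h

    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    # bin centres at the mean pair distance (nominal centre if empty)
    nominal = (np.arange(n_bins) + 0.5) * lag_width
    lag_centres = np.where(counts > 0,
                           dist_sums / np.maximum(counts, 1), nominal)
    return EmpiricalVariogram(
        lags=lag_centres, gamma=gamma, counts=counts,
        direction=direction, cross=cross,
    )


def empirical_variogram(
    grid: Grid,
    lag_width: float | None = None,
    max_lag: float | None = None,
    direction: tuple[float, float] | None = None,
    max_pairs: int | None = 500_000,
    seed: int = 0,
) -> EmpiricalVariogram:
    """Isotropic (or directional) empirical semivariogram of a grid.

    Pairs are enumerated by lattice offset; lag bins have width
    ``lag_width`` (default: one cell size) up to ``max_lag`` (default: a
    third of the shorter grid side).  ``direction`` restricts pairs to an
    (azimuth, tolerance) wedge in degrees.  When the pair count exceeds
    ``max_pairs`` a seeded random cell subsample is used.
    Empty bins are reported with count 0, not interpolated.
    """
    return _variogram(grid, grid, lag_width, max_lag, direction,
                      max_pairs, seed, cross=False)


def cross_variogram(
    grid_a: Grid,
    grid_b: Grid,
    lag_width: float | None = None,
    max_lag: float | None = None,
    max_pairs: int | None = 500_000,
    seed: int = 0,
) -> EmpiricalVariogram:
    """Cross-semivariogram gamma_ab(h) = sum (da)(db) / (2 N(h)).

    Positive values indicate co-varying spatial structure, values near
    zero independence; with ``grid_b = grid_a`` this reduces to the
    ordinary variogram.
    """
    return _variogram(grid_a, grid_b, lag_width, max_lag, None,
                      max_pairs, seed, cross=True)


def _model_curve(family: str, h, nugget, psill, a):
    h = np.asarray(h, dtype=float)
    if family == "spherical":
        hn = np.minimum(h / a, 1.0)
        struct = psill * (1.5 * hn - 0.5 * hn**3)
    else:  # exponential
        struct = psill * (1.0 - np.exp(-h / a))
    return nugget + struct


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramFit:
    """Weighted least-squares fit of a spherical or exponential model.

    Weights are proportional to the pair counts N(h).  Non-negativity of
    nugget and partial sill and positivity of the range are enforced by
    bounds.  Spatial structure finer than the first measured lag is
    indistinguishable from nugget noise, so the structured model is kept
    only when it beats the nugget-only (flat) model in an F-test
    (``structure_pvalue``); otherwise a pure-nugget fit (partial sill 0)
    is returned.  A flat all-zero variogram (constant field) returns the
    degenerate zero fit with ``converged=False``.
    """
    if family not in ("spherical", "exponential"):
        raise ValueError("family must be 'spherical' or 'exponential'")
    ve = emp.nonempty()
    if len(ve.lags) < 4:
        raise ValueError("need at least 4 non-empty lag bins to fit")
    h, g, n = ve.lags, ve.gamma, ve.counts.astype(float)
    if np.allclose(g, 0.0):
        return VariogramFit(family, 0.0, 0.0, float(h[-1]), False, 0.0, 1.0)

    w = np.sqrt(n / n.sum())
    g_max = float(g.max())
    h_max = float(h[-1])
    gn = g / g_max  # fit in normalized units to keep the problem well scaled

    def resid(theta):
        nugget, psill, a = theta
        return w * (_model_curve(family, h, nugget, psill, a) - gn)

    sol = None
    for a0 in (h_max / 10.0, h_max / 3.0, h_max):
        x0 = np.array([max(float(gn[0]) * 0.5, 1e-12),
                       max(1.0 - float(gn[0]) * 0.5, 0.1),
                       a0])
        cand = least_squares(
            resid, x0,
            bounds=([0.0, 0.0, float(h[0]) / 2.0],
                    [np.inf, np.inf, 100.0 * h_max]),
        )
        if sol is None or cand.cost < sol.cost:
            sol = cand
    nugget, psill, a = sol.x[0] * g_max, sol.x[1] * g_max, sol.x[2]
    ss_full = float(np.sum(sol.fun**2)) * g_max**2

    # nugget-only alternative: flat at the weighted mean semivariance
    flat = float(np.sum(w**2 * g) / np.sum(w**2))
    ss_flat = float(np.sum((w * (flat - g)) ** 2))
    k = len(h)
    if ss_full <= 0 or k <= 3:
        p_structure = 0.0
    else:
        F = ((ss_flat - ss_full) / 2.0) / (ss_full / (k - 3))
        p_structure = float(f_dist.sf(max(F, 0.0), 2, k - 3))
    if p_structure > 0.05:
        return VariogramFit(family, flat, 0.0, float(h[0]), bool(sol.success),
                            ss_flat, p_structure)
    return VariogramFit(
        family=family,
        nugget=float(nugget),
        partial_sill=float(psill),
        range_param=float(a),
        converged=bool(sol.success),
        residual_ss=ss_full,
        structure_pvalue=p_structure,
    )


def relative_structural_variance(fit: VariogramFit) -> float:
    """RSV = 100 * partial_sill / (partial_sill + nugget), in percent.

    100% means the variance is entirely spatially structured, 0% pure
    random noise ("a variogram consisting of only a nugget").
    """
    sill = fit.nugget + fit.partial_sill
    if sill <= 0:
        raise ValueError("zero sill: relative structural variance undefined")
    return 100.0 * fit.partial_sill / sill


def optimal_resolution(correlation_range: float) -> float:
    """Optimal observation cell size for a pattern of length scale D_c.

    By the sampling theorem the grid must sample at more than twice the
    highest spatial frequency of interest, so the optimal resolution is
    D_c / 2 (metres).
    """
    if not correlation_range > 0:
        raise ValueError("correlation range must be positive")
    return correlation_range / 2.0


def variogram_sews(
    series: SnapshotSeries,
    family: str = "spherical",
    **kwargs,
) -> pd.DataFrame:
    """Per-snapshot variogram fits along a gradient, as a tidy table.

    Columns: gradient value, nugget, partial_sill, sill, range_param,
    correlation_range, rsv, converged, error (per-snapshot failures are
    recorded, not fatal).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 snapshots")
    rows = []
    for g_value, grid in series:
        row = {series.gradient_name: g_value}
        try:
            emp = empirical_variogram(grid, **kwargs)
            fit = fit_variogram(emp, family=family)
            row.update(
                nugget=fit.nugget, partial_sill=fit.partial_sill,
                sill=fit.sill, range_param=fit.range_param,
                correlation_range=fit.correlation_range,
                rsv=fit.rsv if fit.sill > 0 else np.nan,
                converged=fit.converged, error="",
            )
        except (ValueError, RuntimeError) as exc:
            row.update(
                nugget=np.nan, partial_sill=np.nan, sill=np.nan,
                range_param=np.nan, correlation_range=np.nan, rsv=np.nan,
                converged=False, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
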