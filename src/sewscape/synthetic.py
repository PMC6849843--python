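"""Seeded synthetic grids with known statistical structure.

Real early-warning analyses run on classified imagery and vegetation
indices; for testing and demonstration this module generates grids whose
ground truth is known by construction: white noise, Gaussian random
fields with exponential or squared-exponential (Gaussian) covariance,
deterministic patterns (checkerboard, two-block, Gaussian blob) and a
patchy three-class mosaic emulating a semi-arid bare / herbaceous /
wooded landscape.  Every generator is a pure function of its spec,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "FieldSpec",
    "gaussian_random_field",
    "threshold_to_cover",
    "three_phase_mosaic",
    "checkerboard",
    "two_block",
    "gaussian_blob",
]

_FAMILIES = ("white", "exponential", "gaussian")


@dataclass(frozen=True)
class FieldSpec:
    """Specification of a stationary random field on a square grid.

    ``range_m`` is the covariance length scale ``a`` in metres
    (C(h) = variance * exp(-h/a) for the exponential family,
    exp(-(h/a)^2) for the Gaussian family).
    """

    size: int = 64
    cell_size: float = 1.0
    family: str = "exponential"
    range_m: float = 8.0
    variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("size must be at least 8")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.family != "white" and not self.range_m > 0:
            raise ValueError("range_m must be positive")


def gaussian_random_field(spec: FieldSpec) -> Grid:
    """Sample a stationary Gaussian random field by circulant embedding.

    The target covariance is embedded on a torus of twice the grid size,
    its spectrum obtained by FFT; tiny negative eigenvalues from the
    embedding are clipped to zero (the approximation error is negligible
    at the default sizes).  The returned field has (population) mean 0
    and variance close to ``spec.variance``.
    """
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    if spec.family == "white" or spec.variance == 0:
        vals = rng.standard_normal((n, n)) * np.sqrt(spec.variance)
        return Grid(vals, cell_size=spec.cell_size, kind="continuous")

    m = 2 * n  # embedding torus
    idx = np.arange(m)
    d = np.minimum(idx, m - idx) * spec.cell_size
    hy, hx = np.meshgrid(d, d, indexing="ij")
    h = np.hypot(hy, hx)
    if spec.family == "exponential":
        cov = spec.variance * np.exp(-h / spec.range_m)
    else:
        cov = spec.variance * np.exp(-((h / spec.range_m) ** 2))
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
    # real part of F(sqrt(lam) xi)/m has exactly the target covariance for
    # complex xi with unit-variance real and imaginary parts
    field = np.fft.fft2(np.sqrt(lam / (m * m)) * noise)
    vals = field.real[:n, :n]
    return Grid(vals, cell_size=spec.cell_size, kind="continuous")


def threshold_to_cover(grid: Grid, cover: float) -> Grid:
    """Binarize a continuous grid at the quantile giving the target cover.

    The threshold is the empirical (1 - cover) quantile of the valid
    cells, so the realized cover of state 1 matches ``cover`` to within
    one cell (exactly, for distinct cell values).
    """
    if not 0 < cover < 1:
        raise ValueError("cover must lie strictly between 0 and 1")
    vals = grid.unmasked_values().astype(float)
    if np.ptp(vals) == 0:
        raise ValueError("cannot threshold a constant field")
    k = int(round((1.0 - cover) * vals.size))
    k = min(max(k, 0), vals.size - 1)
    threshold = np.partition(vals, k)[k]
    binary = (grid.values >= threshold).astype(float)
    return Grid(binary, cell_size=grid.cell_size, mask=grid.mask.copy(),
                kind="binary")


def three_phase_mosaic(
    spec: FieldSpec,
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> Grid:
    """Patchy categorical map with three classes at given cover fractions.

    Two nested quantile thresholds of one structured random field produce
    classes 1, 2, 3 (in increasing field value), each covering its
    requested fraction to within one cell.  Class 2 sits spatially
    between 1 and 3, mimicking an intermediate (e.g. herbaceous) state
    between bare and wooded ground.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr <= 0) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must be three positive numbers summing to 1")
    field = gaussian_random_field(spec)
    vals = field.values.ravel()
    order = np.argsort(vals, kind="stable")
    n = vals.size
    k1 = int(round(fr[0] * n))
    k2 = int(round((fr[0] + fr[1]) * n))
    labels = np.empty(n, dtype=int)
    labels[order[:k1]] = 1
    labels[order[k1:k2]] = 2
    labels[order[k2:]] = 3
    return Grid(
        labels.reshape(field.shape), cell_size=spec.cell_size,
        kind="categorical", labels={1: "class 1", 2: "class 2", 3: "class 3"},
    )


def checkerboard(size: int = 16, cell_size: float = 1.0) -> Grid:
    """Alternating 0/1 pattern: the archetype of pure fine-scale structure."""
    r, c = np.indices((size, size))
    return Grid(((r + c) % 2).astype(float), cell_size=cell_size, kind="binary")


def two_block(size: int = 16, cell_size: float = 1.0) -> Grid:
    """Left half 0, right half 1: the archetype of coarse structure."""
    vals = np.zeros((size, size))
    vals[:, size // 2:] = 1.0
    return Grid(vals, cell_size=cell_size, kind="binary")


def gaussian_blob(size: int = 64, width_frac: float = 0.25,
                  cell_size: float = 1.0) -> Grid:
    """A single centred Gaussian bump covering roughly a quarter of the grid."""
    r, c = np.indices((size, size))
    centre = (size - 1) / 2.0
    w = width_frac * size
    vals = np.exp(-(((r - centre) ** 2 + (c - centre) ** 2) / (2.0 * w**2)))
    return Grid(vals, cell_size=cell_size, kind="continuous")
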