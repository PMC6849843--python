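"""Turning raw snapshots into analysis-ready state maps.

Categorical land-cover maps and thresholded vegetation indices are binary
or multi-state grids, and binary data carry a pitfall for early-warning
analysis: spatial variance and skewness are deterministic functions of the
mean cover m alone (var = m(1-m), skew = (1-2m)/sqrt(m(1-m))), so their
"trends" along a gradient may reflect nothing but the changing mean.
This module provides the remedies: coarse-graining to semi-continuous
cover maps, with the aggregation factor chosen as the smallest one at
which the cell-value distribution becomes unimodal (Hartigan dip test),
plus class merging and binarization utilities whose cover bookkeeping is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._dip import dip_statistic, dip_test
from .grid import Grid

__all__ = [
    "binarize",
    "merge_classes",
    "coarse_grain",
    "dip_test",
    "dip_statistic",
    "select_coarse_grain",
    "binary_moment_expectation",
    "ClassMergeSpec",
    "CoarseGrainReport",
]


@dataclass(frozen=True)
class ClassMergeSpec:
    """Total mapping from input class labels to output state labels."""

    mapping: Mapping[int, int]

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) < 2:
            raise ValueError("merge spec must produce at least two output states")


def binarize(grid: Grid, threshold: float, direction: str = ">=") -> Grid:
    """Threshold a continuous grid into a {0, 1} state map.

    ``direction`` '>=' marks cells at or above the threshold as state 1,
    '<=' the reverse.  The missing-value mask is propagated.
    """
    if grid.kind != "continuous":
        raise ValueError("binarize expects a continuous grid")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")
    if direction == ">=":
        vals = (grid.values >= threshold).astype(float)
    else:
        vals = (grid.values <= threshold).astype(float)
    return Grid(vals, cell_size=grid.cell_size, mask=grid.mask.copy(), kind="binary")


def merge_classes(grid: Grid, spec: ClassMergeSpec) -> Grid:
    """Relabel a categorical grid according to a class-merge specification.

    Cover is additive: the cover of any output state equals the summed
    cover of the input classes mapped onto it.  Merging decisions matter —
    aggregating an intermediate land-cover state into the "vegetated"
    rather than the "bare" state changes every spatial indicator of the
    focal state.
    """
    if grid.kind != "categorical":
        raise ValueError("merge_classes expects a categorical grid")
    present = np.unique(grid.values[~grid.mask])
    unmapped = [int(label) for label in present if int(label) not in spec.mapping]
    if unmapped:
        raise ValueError(f"labels {unmapped} not covered by the merge spec")
    out = grid.values.copy()
    for src, dst in spec.mapping.items():
        out[grid.values == src] = dst
    out_states = set(spec.mapping.values())
    kind = "binary" if out_states <= {0, 1} else "categorical"
    return Grid(
        out.astype(float if kind == "binary" else out.dtype),
        cell_size=grid.cell_size,
        mask=grid.mask.copy(),
        kind=kind,
    )


def coarse_grain(grid: Grid, factor: int) -> Grid:
    """Aggregate a grid by block means over non-overlapping factor x factor blocks.

    Mask-aware: block means are taken over the valid cells of each block,
    and a fully missing block stays missing.  Trailing rows/columns that do
    not fill a complete block are dropped.  The output cell size is
    ``factor`` times the input cell size.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    nr, nc = grid.shape
    if factor > nr or factor > nc:
        raise ValueError(f"factor {factor} exceeds grid dimensions {grid.shape}")
    if factor == 1:
        out = grid.copy()
        out.kind = "continuous"
        return out
    nr2, nc2 = nr // factor, nc // factor
    vals = grid.values[: nr2 * factor, : nc2 * factor].astype(float)
    valid = (~grid.mask[: nr2 * factor, : nc2 * factor]).astype(float)
    vals = np.where(valid > 0, vals, 0.0)
    blocks = vals.reshape(nr2, factor, nc2, factor)
    counts = valid.reshape(nr2, factor, nc2, factor).sum(axis=(1, 3))
    sums = blocks.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Grid(
        means,
        cell_size=grid.cell_size * factor,
        mask=counts == 0,
        kind="continuous",
    )


@dataclass
class CoarseGrainReport:
    """Per-factor dip-test report from :func:`select_coarse_grain`."""

    chosen: int | None
    rows: list[dict]  # factor, dip, p, n_cells


def select_coarse_grain(
    grid: Grid,
    factors=None,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> CoarseGrainReport:
    """Smallest aggregation factor whose value distribution is unimodal.

    Each candidate factor is applied with :func:`coarse_grain` and the
    resulting cell values are dip-tested; the chosen factor is the first
    whose test fails to reject unimodality at ``alpha``.  If none
    qualifies, ``chosen`` is ``None`` (the full report is returned either
    way).  A degenerate (constant) distribution counts as unimodal.
    """
    if grid.kind != "binary":
        raise ValueError("select_coarse_grain expects a binary grid")
    if factors is None:
        factors = range(1, max(2, min(grid.shape) // 4) + 1)
    factors = sorted(int(f) for f in factors)
    rows: list[dict] = []
    chosen: int | None = None
    for f in factors:
        cg = coarse_grain(grid, f)
        vals = cg.unmasked_values()
        if vals.size < 4 or np.ptp(vals) == 0:
            d, p = 0.0, 1.0
        else:
            d, p = dip_test(vals, n_boot=n_boot, seed=seed)
        rows.append({"factor": f, "dip": d, "p": p, "n_cells": int(vals.size)})
        if chosen is None and p > alpha:
            chosen = f
    return CoarseGrainReport(chosen=chosen, rows=rows)


def binary_moment_expectation(m: float) -> tuple[float, float]:
    """Bernoulli variance and skewness implied by mean cover ``m``.

    var = m(1-m); skew = (1-2m)/sqrt(m(1-m)).  These are exactly the
    population moments of *any* binary grid with mean cover m — which is
    why raw variance/skewness trends on binary maps must be read against
    this baseline.  m in {0, 1} is degenerate (zero variance, undefined
    skewness) and rejected.
    """
    if not 0 < m < 1:
        raise ValueError("mean cover must lie strictly between 0 and 1")
    var = m * (1.0 - m)
    skew = (1.0 - 2.0 * m) / np.sqrt(var)
    return float(var), float(skew)
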