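"""Null models: permutation envelopes and covariate-association screens.

An indicator value on a single snapshot is hard to read without a
reference: the permutation null scrambles the cells of the snapshot
(destroying all spatial structure while preserving the value
distribution) and recomputes the indicator on each replicate, giving an
empirical confidence envelope.  Indicators that are functions of the
value distribution alone (mean, variance, skewness) are invariant under
permutation; the machinery detects this and flags them instead of
reporting a meaningless degenerate interval as if it were informative.

Before attributing spatial structure of a state map to internal dynamics,
it should also be checked that the state is not simply tracking an
environmental template (soils, terrain).  ``covariate_association`` runs
a chi-square independence screen between a state map and a categorical
covariate map.  Note the caveat: spatial autocorrelation inflates the
effective sample size, so significance is anti-conservative; the test is
a screen, not a calibrated inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .grid import Grid
from .metrics import METRICS, PERMUTATION_INVARIANT, morans_i, spectral_density_ratio

__all__ = ["NullEnvelope", "permutation_null", "covariate_association"]


@dataclass
class NullEnvelope:
    """Permutation-null envelope for one indicator on one snapshot."""

    metric: str
    observed: float
    null_values: np.ndarray
    lo: float
    hi: float
    coverage: float
    outside: bool
    permutation_invariant: bool


def _compute(metric: str, grid: Grid, periodic: bool) -> float:
    if metric == "morans_i":
        return morans_i(grid, periodic=periodic)
    if metric == "sdr":
        return spectral_density_ratio(grid, fill_masked=True)
    return METRICS[metric](grid)


def permutation_null(
    grid: Grid,
    metric: str,
    n_null: int = 200,
    coverage: float = 0.95,
    seed: int = 0,
    periodic: bool = False,
) -> NullEnvelope:
    """Empirical permutation envelope for ``metric`` on ``grid``.

    ``n_null`` full random permutations of the non-missing cells are
    drawn (seeded), the metric recomputed on each, and the empirical
    (1-coverage)/2 and 1-(1-coverage)/2 quantiles reported.  ``outside``
    flags an observed value beyond the envelope.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    observed = _compute(metric, grid, periodic)

    invariant = metric in PERMUTATION_INVARIANT
    if invariant:
        null_values = np.full(n_null, observed)
    else:
        rng = np.random.default_rng(seed)
        valid = ~grid.mask
        vals = grid.values[valid]
        null_values = np.empty(n_null)
        work = grid.values.astype(float).copy()
        for i in range(n_null):
            work[valid] = rng.permutation(vals)
            g = Grid(work, cell_size=grid.cell_size, mask=grid.mask,
                     kind="continuous")
            null_values[i] = _compute(metric, g, periodic)
    alpha = 1.0 - coverage
    lo, hi = np.quantile(null_values, [alpha / 2, 1.0 - alpha / 2])
    return NullEnvelope(
        metric=metric,
        observed=float(observed),
        null_values=null_values,
        lo=float(lo),
        hi=float(hi),
        coverage=coverage,
        outside=bool(observed < lo or observed > hi),
        permutation_invariant=invariant,
    )


def covariate_association(state: Grid, covariate: Grid,
                          min_expected: float = 5.0):
    """Chi-square screen for association between a state map and a covariate map.

    Builds the cell-count contingency table of state class vs covariate
    class over jointly valid cells and runs Pearson's chi-square test of
    independence.  Covariate classes whose column would leave an expected
    count below ``min_expected`` are pooled (rarest first) and the pooling
    is reported.

    Returns ``(chi2, df, p, table, pooled)`` where ``table`` is a pandas
    DataFrame (rows: state classes, columns: covariate classes) and
    ``pooled`` lists the covariate labels that were merged.
    """
    if state.shape != covariate.shape:
        raise ValueError("state and covariate grids must have the same shape")
    if not np.isclose(state.cell_size, covariate.cell_size):
        raise ValueError("state and covariate grids must share a cell size")
    valid = ~(state.mask | covariate.mask)
    s = state.values[valid].astype(int)
    cov = covariate.values[valid].astype(int)
    if np.unique(cov).size < 2:
        raise ValueError("covariate has a single class: association undefined")
    if np.unique(s).size < 2:
        raise ValueError("state map has a single class: association undefined")
    table = pd.crosstab(pd.Series(s, name="state"), pd.Series(cov, name="covariate"))

    pooled: list[int] = []
    # pool rarest covariate classes until every expected count is large enough
    while table.shape[1] > 2:
        expected = (
            np.outer(table.sum(axis=1), table.sum(axis=0)) / table.values.sum()
        )
        if expected.min() >= min_expected:
            break
        smallest = table.sum(axis=0).idxmin()
        others = [c for c in table.columns if c != smallest]
        runner_up = min(others, key=lambda c: table[c].sum())
        table[runner_up] = table[runner_up] + table[smallest]
        table = table.drop(columns=[smallest])
        pooled.append(int(smallest))
    chi2, p, df, _ = chi2_contingency(table.values, correction=False)
    return float(chi2), int(df), float(p), table, pooled
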