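"""The :class:`Grid` container: a rectangular snapshot of an ecosystem state.

A grid holds a 2-D array of cell values — continuous (a vegetation index,
simulated biomass), binary (vegetated / bare) or categorical (land-cover
classes) — together with the physical cell size in metres and an optional
missing-value mask.  Every analysis routine in the package consumes and
produces grids, so conventions are fixed here once: row 0 is the top of the
map (raster convention), cells are square, and ``mask`` is ``True`` where a
cell is *missing*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["Grid", "SnapshotSeries"]

_KINDS = ("continuous", "binary", "categorical")


@dataclass
class Grid:
    """A rectangular single-band raster with square cells.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values.  Stored as float for continuous/binary grids and as
        integer labels for categorical grids.
    cell_size : float
        Side length of a (square) cell in metres.
    mask : ndarray of bool, optional
        ``True`` marks missing cells.  Defaults to all-valid.
    kind : {"continuous", "binary", "categorical"}
    labels : mapping, optional
        Label -> name table for categorical grids.
    """

    values: np.ndarray
    cell_size: float = 1.0
    mask: np.ndarray | None = None
    kind: str = "continuous"
    labels: Mapping[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
        if self.kind == "binary":
            vals = self.unmasked_values()
            if vals.size and not np.isin(vals, (0, 1)).all():
                raise ValueError("binary grid may only contain 0 and 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        """Number of non-missing cells."""
        return int((~self.mask).sum())

    def unmasked_values(self) -> np.ndarray:
        """Flat array of the non-missing cell values."""
        return self.values[~self.mask]

    def mean(self) -> float:
        """Spatial mean over non-missing cells (mean cover for binary grids)."""
        if self.n_valid == 0:
            raise ValueError("grid has no valid cells")
        return float(self.unmasked_values().mean())

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class SnapshotSeries:
    """An ordered collection of grids indexed by a stressor/gradient value.

    ``gradient`` is typically the grazing rate ``c`` at which each snapshot
    was taken, but any numeric gradient coordinate works.
    """

    gradient: list[float]
    grids: list[Grid]
    gradient_name: str = "c"

    def __post_init__(self) -> None:
        if len(self.gradient) != len(self.grids):
            raise ValueError("gradient and grids must have equal length")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(zip(self.gradient, self.grids))
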