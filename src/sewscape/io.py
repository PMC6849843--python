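"""Raster and tabular I/O.

Two single-band raster encodings are supported:

* **ESRI ASCII grid** (``.asc``/``.agr``): the plain-text interchange
  format — header (ncols, nrows, xllcorner, yllcorner, cellsize,
  nodata_value) followed by rows of numbers, row 0 at the top.
* **TIFF** (``.tif``/``.tiff``) via :mod:`tifffile`: a single-band image
  whose cell size and nodata value travel in a small JSON payload in the
  ImageDescription tag (plain TIFF, no geo-referencing beyond the cell
  size).

Cells are square and sized in metres.  Integer-typed rasters load as
categorical grids, floats as continuous (overridable).  Tables are CSV,
UTF-8, '.' decimal.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = ["read_grid", "write_grid", "write_table", "read_manifest"]

_NODATA = -9999.0


def _infer_kind(values: np.ndarray, kind: str | None) -> str:
    if kind is not None:
        return kind
    if np.issubdtype(values.dtype, np.integer):
        return "categorical"
    return "continuous"


def _read_asc(path: Path) -> tuple[np.ndarray, float, float | None]:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid {path} is missing '{key}'")
    values = np.array(rows, dtype=float)
    flat = values.ravel()
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if flat.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows}x{ncols} values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    return values, header["cellsize"], header.get("nodata_value")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_grid(path, band: int = 1, kind: str | None = None) -> Grid:
    """Read a single-band raster (ESRI ASCII grid or TIFF) as a Grid.

    Nodata cells become the missing-value mask.  ``kind`` overrides the
    dtype-based continuous/categorical inference.  For multi-page TIFFs,
    ``band`` selects the (1-based) page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".agr", ".txt"):
        values, cell_size, nodata = _read_asc(path)
        mask = np.isclose(values, nodata) if nodata is not None else None
        valid = values[~mask] if mask is not None else values
        # ASCII carries no dtype: treat small all-integer label sets as
        # categorical unless the caller says otherwise
        is_labels = (
            valid.size > 0
            and np.all(np.mod(valid, 1) == 0)
            and np.ptp(valid) < 1000
        )
        inferred = kind or ("categorical" if is_labels else "continuous")
    elif suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            n_pages = len(tf.pages)
            if n_pages > 1 and band is None:
                raise ValueError(f"{path} has {n_pages} bands; select one")
            page = tf.pages[band - 1]
            values = page.asarray()
            meta = {}
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (TypeError, json.JSONDecodeError):
                    meta = {}
        if values.ndim == 3:
            if values.shape[2] < band:
                raise ValueError(f"band {band} out of range")
            values = values[:, :, band - 1]
        cell_size = float(meta.get("cell_size", 1.0))
        if not np.isclose(
            cell_size, float(meta.get("cell_size_y", cell_size))
        ):
            raise ValueError("anisotropic cell sizes are not supported")
        nodata = meta.get("nodata")
        mask = np.isclose(values.astype(float), nodata) if nodata is not None else None
        inferred = _infer_kind(values, kind)
    else:
        raise ValueError(
            f"unsupported raster format {suffix!r} (use .asc or .tif)"
        )
    values = values.astype(int) if inferred == "categorical" else values.astype(float)
    return Grid(values, cell_size=float(cell_size), mask=mask, kind=inferred)


def write_grid(grid: Grid, path, fmt: str | None = None) -> None:
    """Write a Grid losslessly as ESRI ASCII (.asc) or TIFF (.tif)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    values = grid.values.astype(float).copy()
    has_mask = grid.mask.any()
    if has_mask:
        values[grid.mask] = _NODATA
    if fmt in ("asc", "agr", "txt"):
        nr, nc = grid.shape
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"ncols {nc}\n")
            fh.write(f"nrows {nr}\n")
            fh.write("xllcorner 0.0\n")
            fh.write("yllcorner 0.0\n")
            fh.write(f"cellsize {float(grid.cell_size)!r}\n")
            fh.write(f"nodata_value {_NODATA!r}\n")
            for row in values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    elif fmt in ("tif", "tiff"):
        import tifffile

        meta = {"cell_size": grid.cell_size, "kind": grid.kind}
        if has_mask:
            meta["nodata"] = _NODATA
        tifffile.imwrite(path, values, description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported raster format {fmt!r}")


def write_table(rows, path) -> None:
    """Write a table (DataFrame or list of dicts) as UTF-8 CSV with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, index=False)
        return
    rows = list(rows)
    if not rows:
        path.write_text("", encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path) -> pd.DataFrame:
    """Read a snapshot manifest CSV (columns: filename, gradient value, ...).

    Paths are resolved relative to the manifest location and checked for
    existence; the gradient column must be numeric.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "filename" not in df.columns:
        raise ValueError(f"manifest {path} lacks a 'filename' column")
    base = path.parent
    resolved = []
    for fn in df["filename"]:
        p = (base / fn) if not Path(fn).is_absolute() else Path(fn)
        if not p.exists():
            raise FileNotFoundError(f"manifest entry not found: {p}")
        resolved.append(str(p))
    df = df.copy()
    df["filename"] = resolved
    gradient_cols = [c for c in df.columns if c in ("c", "gradient")]
    for col in gradient_cols:
        df[col] = pd.to_numeric(df[col])
    return df
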