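"""YAML-configured analysis pipelines.

A config file describes an ordered set of stages — ``simulate``,
``preprocess``, ``metrics``, ``nulls``, ``variogram`` — each optional.
Stages run in that order, pass grids forward, log their parameters and
seeds, and leave a ``run_record.json`` next to the outputs so any result
can be reproduced from the record alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .grazing import ModelParams, gradient_snapshots
from .grid import SnapshotSeries
from .metrics import sews_summary
from .nulls import permutation_null
from .preprocess import binarize, coarse_grain, select_coarse_grain
from .variogram import variogram_sews

log = logging.getLogger("sewscape")

_STAGES = ("simulate", "preprocess", "metrics", "nulls", "variogram")


class ConfigError(ValueError):
    """Config schema violation, reported with the offending field path."""


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"{path}.{key}: unknown field")


def run_config(config_path, out_dir=None) -> dict:
    """Execute the pipeline described by a YAML config file.

    Returns the run record (also written to ``<out>/run_record.json``).
    An empty config is a no-op with a log entry.
    """
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("top level: expected a mapping of stage sections")
    _check_keys(cfg, set(_STAGES) | {"out", "seed"}, "config")

    out = Path(out_dir or cfg.get("out", config_path.parent / "sewscape_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    record: dict = {"config": str(config_path), "seed": seed, "stages": []}

    series: SnapshotSeries | None = None

    if "simulate" in cfg:
        sec = dict(cfg["simulate"] or {})
        _check_keys(
            sec,
            {"r", "K", "B0", "D", "sigma", "dt", "L", "c_values", "burn_in"},
            "simulate",
        )
        c_values = [float(c) for c in sec.pop("c_values", [5, 10, 15, 20])]
        burn_in = float(sec.pop("burn_in", 100.0))
        params = ModelParams(seed=seed, **{k: v for k, v in sec.items()})
        series = gradient_snapshots(params, c_values, burn_in=burn_in)
        manifest = []
        for c, grid in series:
            fn = f"snapshot_c{c:g}.asc"
            sio.write_grid(grid, out / fn)
            manifest.append({"filename": fn, "c": c, "seed": seed,
                             "burn_in": burn_in})
        sio.write_table(manifest, out / "manifest.csv")
        record["stages"].append(
            {"stage": "simulate", "params": asdict(params),
             "c_values": c_values, "burn_in": burn_in,
             "outputs": [m["filename"] for m in manifest]}
        )
        log.info("simulate: %d snapshots -> %s", len(series), out)

    if "preprocess" in cfg and series is not None:
        sec = dict(cfg["preprocess"] or {})
        _check_keys(sec, {"binarize_threshold", "coarse_factor", "auto",
                          "alpha"}, "preprocess")
        grids = []
        for grid in series.grids:
            g = grid
            if "binarize_threshold" in sec:
                g = binarize(g, float(sec["binarize_threshold"]))
            if sec.get("auto"):
                report = select_coarse_grain(
                    g, alpha=float(sec.get("alpha", 0.05)), seed=seed
                )
                factor = report.chosen or 1
                g = coarse_grain(g, factor)
            elif "coarse_factor" in sec:
                g = coarse_grain(g, int(sec["coarse_factor"]))
            grids.append(g)
        series = SnapshotSeries(series.gradient, grids, series.gradient_name)
        record["stages"].append({"stage": "preprocess", "options": sec})
        log.info("preprocess: %s", sec)

    if "metrics" in cfg and series is not None:
        sec = dict(cfg["metrics"] or {})
        _check_keys(sec, {"periodic"}, "metrics")
        rows = []
        for c, grid in series:
            s = sews_summary(grid, periodic=bool(sec.get("periodic", False)))
            rows.append({
                "c": c, "mean_cover": s.mean_cover,
                "spatial_variance": s.spatial_variance,
                "spatial_skewness": s.spatial_skewness,
                "morans_i": s.morans_i, "sdr": s.sdr,
            })
        sio.write_table(rows, out / "sews.csv")
        record["stages"].append({"stage": "metrics", "outputs": ["sews.csv"]})
        log.info("metrics: sews.csv (%d rows)", len(rows))

    if "nulls" in cfg and series is not None:
        sec = dict(cfg["nulls"] or {})
        _check_keys(sec, {"metrics", "n_null", "coverage"}, "nulls")
        metric_names = sec.get("metrics", ["morans_i", "sdr"])
        rows = []
        for c, grid in series:
            for m in metric_names:
                env = permutation_null(
                    grid, m, n_null=int(sec.get("n_null", 200)),
                    coverage=float(sec.get("coverage", 0.95)), seed=seed,
                )
                rows.append({
                    "c": c, "metric": m, "observed": env.observed,
                    "null_lo": env.lo, "null_hi": env.hi,
                    "outside": env.outside,
                    "permutation_invariant": env.permutation_invariant,
                })
        sio.write_table(rows, out / "nulls.csv")
        record["stages"].append({"stage": "nulls", "outputs": ["nulls.csv"]})
        log.info("nulls: nulls.csv (%d rows)", len(rows))

    if "variogram" in cfg and series is not None:
        sec = dict(cfg["variogram"] or {})
        _check_keys(sec, {"family", "max_lag"}, "variogram")
        table = variogram_sews(
            series, family=sec.get("family", "spherical"),
            max_lag=sec.get("max_lag"), seed=seed,
        )
        sio.write_table(table, out / "variogram_sews.csv")
        record["stages"].append(
            {"stage": "variogram", "outputs": ["variogram_sews.csv"]}
        )
        log.info("variogram: variogram_sews.csv (%d rows)", len(table))

    if not record["stages"]:
        log.info("empty config: no stages executed")
    with open(out / "run_record.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, default=_json_default)
    return record


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
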