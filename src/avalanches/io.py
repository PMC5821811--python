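"""File formats: raster CSV, catalog TSV, result JSON.

Raster CSV dialect: comma-delimited, UTF-8, header ``neuron_id,frame``
(integer or real frames) or ``neuron_id,time_s`` (seconds); lines starting
with '#' are comments; an optional ``#n_neurons=K`` comment declares the
network size (otherwise max id + 1 is used).  Duplicate (neuron, time)
rows are deduplicated with a logged count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RasterParseError
from .extraction import AvalancheCatalog, SpikeRaster

__all__ = ["read_raster", "write_raster", "read_catalog", "write_catalog",
           "write_json", "write_exponent_map"]

log = logging.getLogger("avalanches")


def read_raster(path, frame_dt: float = 0.030) -> SpikeRaster:
    """Read a spike raster from the shared CSV dialect."""
    path = Path(path)
    declared_n = None
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "n_neurons=" in line:
                try:
                    declared_n = int(line.split("n_neurons=")[1].strip())
                except ValueError as exc:
                    raise RasterParseError(f"{path}: malformed n_neurons comment: {line!r}") from exc
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise RasterParseError(f"{path}: {exc}") from exc

    cols = set(df.columns)
    if "neuron_id" not in cols or not ({"frame", "time_s"} & cols):
        raise RasterParseError(
            f"{path}: expected columns neuron_id + (frame|time_s), got {sorted(cols)}"
        )
    time_col = "frame" if "frame" in cols else "time_s"
    bad = df[df[["neuron_id", time_col]].isna().any(axis=1)]
    if len(bad):
        raise RasterParseError(f"{path}: unreadable row at data line {bad.index[0] + 2}")
    times = df[time_col].to_numpy(dtype=np.float64)
    if np.any(times < 0):
        line = int(np.flatnonzero(times < 0)[0]) + 2
        raise RasterParseError(f"{path}: negative time at data line {line}")
    if time_col == "time_s":
        times = times / frame_dt
    ids = df["neuron_id"].to_numpy(dtype=np.int64)

    dedup = pd.DataFrame({"id": ids, "t": times}).drop_duplicates()
    n_dropped = len(df) - len(dedup)
    if n_dropped:
        log.warning("%s: dropped %d duplicate (neuron, time) rows", path, n_dropped)
    ids, times = dedup["id"].to_numpy(), dedup["t"].to_numpy()

    n_neurons = declared_n if declared_n is not None else (int(ids.max()) + 1 if ids.size else 1)
    return SpikeRaster(neuron_ids=ids, times=times, n_neurons=n_neurons, frame_dt=frame_dt)


def write_raster(raster: SpikeRaster, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#n_neurons={raster.n_neurons}\n")
        fh.write(f"#frame_dt={raster.frame_dt}\n")
        fh.write("neuron_id,frame\n")
        for nid, t in zip(raster.neuron_ids, raster.times):
            frame = int(t) if float(t).is_integer() else repr(float(t))
            fh.write(f"{nid},{frame}\n")


def write_catalog(catalog: AvalancheCatalog, path) -> None:
    """Catalog TSV: index, size, duration and optional flag columns."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog(path) -> AvalancheCatalog:
    df = pd.read_csv(path, sep="\t")
    kwargs = {}
    if "capped_flag" in df.columns:
        kwargs["capped"] = df["capped_flag"].to_numpy(dtype=bool)
    if "participation" in df.columns:
        kwargs["participations"] = df["participation"].to_numpy(dtype=np.float64)
    if "sse_flag" in df.columns:
        kwargs["sse_flags"] = df["sse_flag"].to_numpy(dtype=bool)
    return AvalancheCatalog(
        sizes=df["size"].to_numpy(dtype=np.int64),
        durations=df["duration"].to_numpy(dtype=np.int64),
        **kwargs,
    )


def write_exponent_map(emap, path_prefix) -> None:
    """Exponent and p-value grids as TSV matrices (rows: x_low, cols: x_high)."""
    prefix = Path(path_prefix)
    for name, grid in (("exponent", emap.exponent_grid), ("pvalue", emap.p_grid)):
        df = pd.DataFrame(grid, index=emap.x_low_grid, columns=emap.x_high_grid)
        df.index.name = "x_low\\x_high"
        df.to_csv(f"{prefix}_{name}.tsv", sep="\t")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
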