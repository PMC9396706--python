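"""Delimited-text readers/writers for tracks, rasters and reports.

Tracking schema (CSV): ``animal_id, timestamp (ISO-8601 UTC), lon, lat,
lc_class[, true_lon, true_lat]``.  Rasters are whitespace-delimited grids
with a one-line JSON header (prefixed ``#``) carrying bbox, cell size,
variable and season; one file per variable per season.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import CLIMATE_VARS, ClimateRaster

TRACK_COLUMNS = ["animal_id", "timestamp", "lon", "lat", "lc_class"]


def write_tracking(trajs, path) -> None:
    """Write one or more trajectory frames to the tracking CSV schema."""
    if isinstance(trajs, pd.DataFrame):
        trajs = [trajs]
    df = pd.concat(trajs, ignore_index=True)
    cols = TRACK_COLUMNS + [c for c in ("true_lon", "true_lat", "pred_x_km",
                                        "pred_y_km", "pred_var_km2")
                            if c in df.columns]
    out = df[cols].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tracking(path) -> list[pd.DataFrame]:
    """Read the tracking CSV into per-animal trajectories, sorted by time.

    Malformed rows, unparseable timestamps and duplicated timestamps within
    an animal raise with the offending line number(s).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True,
                                         format="ISO8601")
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: unparseable timestamp: {err}") from None
    for col in ("lon", "lat"):
        bad = df[col].isna() | ~np.isfinite(df[col].astype(float))
        if bad.any():
            lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"{path}: malformed {col} at line(s) {lines[:5]}")
    out = []
    for _, grp in df.groupby("animal_id", sort=True):
        dup = grp["timestamp"].duplicated()
        if dup.any():
            lines = (grp.index[dup] + 2).tolist()
            raise ValueError(
                f"{path}: duplicated timestamp(s) for animal "
                f"{grp['animal_id'].iloc[0]!r} at line(s) {lines[:5]}")
        out.append(grp.sort_values("timestamp").reset_index(drop=True))
    return out


def write_raster(raster: ClimateRaster, directory, season: str | None = None
                 ) -> list[Path]:
    """Write each climate variable of a raster to ``<season>_<var>.grid``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    season = season or raster.season or "season"
    paths = []
    for var in CLIMATE_VARS:
        header = {"west": raster.west, "south": raster.south,
                  "cell_size": raster.cell_size, "variable": var,
                  "season": season, "shape": list(raster.shape)}
        p = directory / f"{season}_{var}.grid"
        with open(p, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            np.savetxt(fh, raster.values[var], fmt="%.6g")
        paths.append(p)
    return paths


def read_raster(directory, season: str) -> ClimateRaster:
    """Read the four per-variable grid files of one season back."""
    directory = Path(directory)
    values = {}
    meta = None
    for var in CLIMATE_VARS:
        p = directory / f"{season}_{var}.grid"
        with open(p) as fh:
            header = json.loads(fh.readline().lstrip("# "))
            values[var] = np.loadtxt(fh).reshape(header["shape"])
        meta = header
    return ClimateRaster(west=meta["west"], south=meta["south"],
                         cell_size=meta["cell_size"], values=values,
                         season=season)


def _round_sig(x, sig=6):
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return None
        return float(f"{float(x):.{sig}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def write_report(obj: dict, path, sig: int = 6) -> None:
    """JSON report with all floats at 6 significant digits (deterministic)."""
    with open(path, "w") as fh:
        json.dump(_round_sig(obj, sig), fh, indent=1, sort_keys=True)
        fh.write("\n")
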