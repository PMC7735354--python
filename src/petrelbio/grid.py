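"""Grid-standardised foraging effort and environmental matching.

Time spent foraging, localised on the 1 s interpolated track, is summed
into half-open square cells ``[k*cell, (k+1)*cell)`` anchored at 0 deg
(default cell 0.04 deg, ~4 km^2) and standardised to percent of the
trip's total foraging time.  Covariate layers (xarray DataArrays on
lat/lon[/time] grids) are matched by nearest neighbour in space and by the
temporally nearest layer to each cell's mean foraging timestamp.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .errors import SchemaError

log = logging.getLogger("petrelbio")


def grid_foraging_time(
    track: pd.DataFrame, is_foraging: np.ndarray, cell_deg: float = 0.04
) -> pd.DataFrame:
    """Standardised percent of foraging time per grid cell.

    ``track`` is a dense (1 s) interpolated track with timestamp/lat/lon;
    ``is_foraging`` flags each track second.  Returns one row per occupied
    cell with indices, cell-centre coordinates, seconds, percent and the
    mean foraging timestamp in that cell.
    """
    flags = np.asarray(is_foraging, bool)
    n = min(len(track), len(flags))
    sub = track.iloc[:n][flags[:n]]
    if len(sub) == 0:
        log.info("no foraging seconds to grid")
        return pd.DataFrame(
            columns=["i", "j", "lat_center", "lon_center", "seconds", "pct", "mid_time"]
        )
    i = np.floor(sub["lat"].to_numpy(float) / cell_deg).astype(int)
    j = np.floor(sub["lon"].to_numpy(float) / cell_deg).astype(int)
    df = pd.DataFrame({"i": i, "j": j, "timestamp": sub["timestamp"].to_numpy()})
    grouped = df.groupby(["i", "j"]).agg(
        seconds=("timestamp", "size"), mid_time=("timestamp", "mean")
    )
    out = grouped.reset_index()
    out["lat_center"] = (out["i"] + 0.5) * cell_deg
    out["lon_center"] = (out["j"] + 0.5) * cell_deg
    out["pct"] = 100.0 * out["seconds"] / out["seconds"].sum()
    return out[["i", "j", "lat_center", "lon_center", "seconds", "pct", "mid_time"]]


def match_environment(
    cells: pd.DataFrame, layers: dict[str, xr.DataArray]
) -> pd.DataFrame:
    """Join covariate values onto grid cells.

    Each layer must carry ``lat`` and ``lon`` coordinates (and optionally
    ``time``).  For every cell, the spatially nearest grid node of the
    temporally nearest slice is used; cells outside a layer's extent get a
    missing value, never a silent zero.
    """
    out = cells.copy()
    for name, da in layers.items():
        if "lat" not in da.coords or "lon" not in da.coords:
            raise SchemaError(f"layer {name!r} lacks lat/lon georeference")
        tol_lat = _tolerance(da["lat"].values)
        tol_lon = _tolerance(da["lon"].values)
        vals = np.full(len(out), np.nan)
        for k, row in enumerate(out.itertuples()):
            slice_ = da
            if "time" in da.dims:
                t = pd.Timestamp(row.mid_time)
                if t.tzinfo is not None:
                    t = t.tz_convert("UTC").tz_localize(None)
                slice_ = da.sel(time=np.datetime64(t), method="nearest")
            try:
                v = slice_.sel(
                    lat=row.lat_center,
                    lon=row.lon_center,
                    method="nearest",
                    tolerance=max(tol_lat, tol_lon),
                )
                vals[k] = float(v)
            except KeyError:
                vals[k] = np.nan
        out[name] = vals
    return out


def _tolerance(coord: np.ndarray) -> float:
    if len(coord) < 2:
        return 0.5
    return float(np.max(np.abs(np.diff(coord))))


def covariate_correlations(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between covariates (reported to
    the user; nothing is dropped automatically)."""
    return table[covariates].corr(method="spearman")
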