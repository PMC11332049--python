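"""Readers and writers for observation tables and gridded temperatures.

Observation CSVs carry one presence-only record per row (species,
longitude, latitude, ISO 8601 date); rows with unparseable dates or
out-of-range coordinates are dropped and counted. Temperature grids are
read from NetCDF (lat/lon/time layout) or long CSV and re-scaled to the
analysis grid by averaging the source pixels intersecting each cell.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "species": "species",
    "lon": "longitude",
    "lat": "latitude",
    "date": "date",
}


def read_observations(paths, column_map: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Read and pool observation CSVs into the canonical table.

    Returns (frame, counts). The frame has columns species, lon, lat, date,
    doy, year; counts records per-source read and dropped rows. ``paths``
    may be a single path or a list (sources are pooled).
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames, counts = [], {"n_read": 0, "n_dropped": 0, "per_source": {}}
    for path in paths:
        raw = pd.read_csv(path)
        missing = [src for src in cmap.values() if src not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        df = pd.DataFrame(
            {
                "species": raw[cmap["species"]].astype(str),
                "lon": pd.to_numeric(raw[cmap["lon"]], errors="coerce"),
                "lat": pd.to_numeric(raw[cmap["lat"]], errors="coerce"),
                "date": pd.to_datetime(raw[cmap["date"]], format="ISO8601", errors="coerce"),
            }
        )
        ok = (
            df["date"].notna()
            & df["lon"].between(-180, 180)
            & df["lat"].between(-90, 90)
        )
        n_read, n_ok = len(df), int(ok.sum())
        counts["n_read"] += n_read
        counts["n_dropped"] += n_read - n_ok
        counts["per_source"][str(path)] = {"read": n_read, "retained": n_ok}
        df = df.loc[ok].copy()
        df["doy"] = df["date"].dt.dayofyear.astype(int)
        df["year"] = df["date"].dt.year.astype(int)
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        frames.append(df)
        logger.info("%s: %d rows read, %d retained", path, n_read, n_ok)
    frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["species", "lon", "lat", "date", "doy", "year"]
    )
    return frame, counts


def write_temperature_netcdf(temps: xr.Dataset, path) -> None:
    """Write a cell x day temperature cube as NetCDF (classic format)."""
    temps.to_netcdf(path, engine="scipy")


def read_temperature_netcdf(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def temperature_cube_to_csv(temps: xr.Dataset, path) -> None:
    """Long-format CSV alternative (cell_id, day, tmin, tmax)."""
    df = temps.to_dataframe().reset_index().rename(columns={"cell": "cell_id"})
    df.to_csv(path, index=False)


def temperature_cube_from_csv(path, year: int | None = None) -> xr.Dataset:
    df = pd.read_csv(path)
    ds = df.set_index(["cell_id", "day"]).to_xarray().rename({"cell_id": "cell"})
    if year is not None:
        ds.attrs["year"] = int(year)
    return ds


def read_temperature_grid(path, grid: GridSpec) -> xr.Dataset:
    """Read an E-OBS-style NetCDF (lat, lon, time) and re-scale to the grid.

    Each analysis cell's daily tmin/tmax is the mean of the source pixels
    whose centres fall in the cell. Leap years are folded to 365 days (Feb 29
    is averaged into DOY 59) so days of year align across years. Raises if
    the source leaves temporal gaps or covers none of the grid.
    """
    with xr.open_dataset(path, engine="scipy") as src:
        src = src.load()
    for var in ("tmin", "tmax"):
        if var not in src:
            raise ValueError(f"{path}: missing variable {var!r}")
    time = pd.to_datetime(src["time"].values)
    doys = time.dayofyear.to_numpy()
    expected = np.arange(1, len(np.unique(doys)) + 1)
    if not np.array_equal(np.sort(np.unique(doys)), expected) or len(doys) < 365:
        missing = sorted(set(range(1, 366)) - set(doys.tolist()))
        raise ValueError(f"{path}: temporal gaps at days {missing[:10]}")
    lon2d, lat2d = np.meshgrid(src["lon"].values, src["lat"].values)
    cells = grid.cell_of_lonlat(lon2d.ravel(), lat2d.ravel())
    inside = cells >= 0
    if not inside.any():
        raise ValueError(f"{path}: no source pixels fall inside the analysis grid")
    out = {}
    for var in ("tmin", "tmax"):
        vals = src[var].transpose("time", "lat", "lon").values.reshape(len(time), -1)
        df = pd.DataFrame(vals[:, inside].T)
        df["cell_id"] = cells[inside]
        cellmeans = df.groupby("cell_id").mean()
        out[var] = cellmeans
    cell_ids = out["tmin"].index.to_numpy()
    tmin = out["tmin"].to_numpy()
    tmax = out["tmax"].to_numpy()
    if len(time) == 366:
        # fold the leap day: average Feb 28/29 into DOY 59, shift the rest
        for arr in (tmin, tmax):
            arr[:, 58] = 0.5 * (arr[:, 58] + arr[:, 59])
        tmin = np.delete(tmin, 59, axis=1)
        tmax = np.delete(tmax, 59, axis=1)
    ds = xr.Dataset(
        {
            "tmin": (("cell", "day"), tmin),
            "tmax": (("cell", "day"), tmax),
        },
        coords={"cell": cell_ids, "day": np.arange(1, tmin.shape[1] + 1)},
        attrs={"year": int(time[0].year)},
    )
    return ds
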