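"""Growing degree days (GDD) and their evaluation at flowering dates.

Thermal time is accumulated as the cumulative sum, from January 1, of
max(0, (tmin + tmax)/2 - base_temp) with a 5 degC default baseline — the
standard agronomic GDD. Evaluating a cell's cumulative GDD at its median
observation date links a phenological shift between years to the shift in
temperature accumulation: a warm year that advances flowering should show
higher accumulated GDD at the (earlier) flowering date when plants only
partially track thermal time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

DEFAULT_BASE_TEMP = 5.0


def gdd_series(temps: xr.Dataset, base_temp: float = DEFAULT_BASE_TEMP) -> xr.DataArray:
    """Cumulative GDD per cell and day from daily tmin/tmax.

    Requires a complete year (days 1..365/366 with no gaps); raises listing
    missing days otherwise.
    """
    days = np.asarray(temps["day"].values)
    n_days = int(days.max())
    expected = np.arange(1, n_days + 1)
    if n_days not in (365, 366) or len(days) != n_days or not np.array_equal(
        np.sort(days), expected
    ):
        missing = sorted(set(range(1, max(n_days, 365) + 1)) - set(days.tolist()))
        raise ValueError(f"temperature cube has day gaps: {missing[:10]}")
    temps = temps.sortby("day")
    tmean = (temps["tmin"] + temps["tmax"]) / 2.0
    if (temps["tmax"] < temps["tmin"]).any():
        raise ValueError("tmax < tmin in temperature cube")
    increment = (tmean - base_temp).clip(min=0.0)
    gdd = increment.cumsum("day")
    gdd.name = "gdd"
    gdd.attrs["base_temp"] = float(base_temp)
    return gdd


def gdd_at_mod(gdd: xr.DataArray, mod_grid: pd.DataFrame) -> pd.DataFrame:
    """Cumulative GDD at each cell's (possibly fractional) MOD.

    GDD is treated as piecewise linear between integer days; a MOD of
    d + f maps to (1-f)*GDD(d) + f*GDD(d+1). Cells present in the MOD grid
    but absent from the GDD cube are skipped with a log entry.
    """
    cube_cells = pd.Index(gdd["cell"].values)
    n_days = gdd.sizes["day"]
    values = gdd.transpose("cell", "day").values
    rows = []
    skipped = 0
    for rec in mod_grid.itertuples(index=False):
        if rec.cell_id not in cube_cells:
            skipped += 1
            continue
        ci = cube_cells.get_loc(rec.cell_id)
        mod = float(np.clip(rec.mod, 1.0, n_days))
        d0 = int(np.floor(mod))
        frac = mod - d0
        g0 = values[ci, d0 - 1]
        g1 = values[ci, min(d0, n_days - 1)] if frac > 0 else g0
        rows.append(
            {
                "species": getattr(rec, "species", None),
                "year": getattr(rec, "year", None),
                "cell_id": rec.cell_id,
                "mod": mod,
                "gdd_at_mod": float(g0 + frac * (g1 - g0)),
            }
        )
    if skipped:
        logger.info("gdd_at_mod: skipped %d cells missing from the GDD cube", skipped)
    return pd.DataFrame(rows, columns=["species", "year", "cell_id", "mod", "gdd_at_mod"])


def gdd_shift(year_a: pd.DataFrame, year_b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell change in GDD-at-MOD between two years (b - a).

    Returns the per-cell table and a per-species summary (median and MAD of
    the shift). The convention pairs with the MOD shift (also b - a): if a
    species flowers earlier in year a, the MOD shift is positive and the
    expected GDD shift is negative (accumulation at flowering was higher in
    the warm year).
    """
    merged = year_a.merge(
        year_b, on=["species", "cell_id"], suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        raise ValueError("no shared cells between the two years")
    merged["delta_gdd"] = merged["gdd_at_mod_b"] - merged["gdd_at_mod_a"]
    per_cell = merged[["species", "cell_id", "gdd_at_mod_a", "gdd_at_mod_b", "delta_gdd"]]
    summary = (
        per_cell.groupby("species")["delta_gdd"]
        .agg(
            median_delta_gdd="median",
            mad_delta_gdd=lambda s: float(np.median(np.abs(s - s.median()))),
            n_cells="size",
        )
        .reset_index()
    )
    return per_cell, summary
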