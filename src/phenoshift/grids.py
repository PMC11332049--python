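"""Equal-area gridding of presence-only observations.

Observations are projected onto a square grid in an equal-area plane
(default 50 x 50 km cells, spherical European LAEA), aggregated per
species x year x cell, and filtered by a minimum per-cell count before
phenometric estimation. Cells use half-open intervals [x, x + cell_size)
with a lower-left origin and row-major cell ids, so every point belongs
to exactly one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import LambertAzimuthalEqualArea

logger = logging.getLogger(__name__)

DEFAULT_CELL_SIZE_M = 50_000.0
DEFAULT_MIN_COUNT = 25


@dataclass(frozen=True)
class GridSpec:
    """A square equal-area grid in a projected plane.

    ``cell_id = row * n_cols + col`` counted from the lower-left origin.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int
    projection: LambertAzimuthalEqualArea = field(default_factory=LambertAzimuthalEqualArea)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def cell_area(self) -> float:
        """Projected area of every cell (m^2); identical for all cells."""
        return self.cell_size**2

    def cell_of_xy(self, x, y):
        """Cell ids for projected coordinates; -1 for points outside the grid."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row * self.n_cols + col, -1)

    def cell_of_lonlat(self, lon, lat):
        x, y = self.projection.forward(lon, lat)
        return self.cell_of_xy(x, y)

    def centroids_xy(self, cell_ids=None):
        """Projected centres (x, y) of the given cells (all cells if None)."""
        ids = np.arange(self.n_cells) if cell_ids is None else np.asarray(cell_ids, int)
        row, col = np.divmod(ids, self.n_cols)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (row + 0.5) * self.cell_size
        return x, y

    def centroids_lonlat(self, cell_ids=None):
        x, y = self.centroids_xy(cell_ids)
        return self.projection.inverse(x, y)

    def cell_polygons(self, cell_ids=None):
        """Shapely polygons of cell footprints in geographic coordinates."""
        from shapely.geometry import Polygon

        ids = np.arange(self.n_cells) if cell_ids is None else np.asarray(cell_ids, int)
        polys = []
        for cid in ids:
            row, col = divmod(int(cid), self.n_cols)
            x0 = self.origin_x + col * self.cell_size
            y0 = self.origin_y + row * self.cell_size
            xs = [x0, x0 + self.cell_size, x0 + self.cell_size, x0]
            ys = [y0, y0, y0 + self.cell_size, y0 + self.cell_size]
            lon, lat = self.projection.inverse(np.array(xs), np.array(ys))
            polys.append(Polygon(zip(lon, lat)))
        return polys


@dataclass
class CellSample:
    """All observation DOYs for one species x year x grid cell."""

    species: str
    year: int
    cell_id: int
    doys: np.ndarray

    @property
    def n(self) -> int:
        return len(self.doys)


def build_grid(
    bbox: tuple[float, float, float, float],
    cell_size: float = DEFAULT_CELL_SIZE_M,
    projection: LambertAzimuthalEqualArea | None = None,
) -> GridSpec:
    """Build an equal-area grid covering a geographic bounding box.

    Parameters
    ----------
    bbox:
        (lon_min, lat_min, lon_max, lat_max) in decimal degrees.
    cell_size:
        Cell edge length in metres.
    projection:
        Equal-area projection; defaults to the European spherical LAEA.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError(f"degenerate bounding box: {bbox}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    proj = projection or LambertAzimuthalEqualArea()
    # Sample the bbox boundary densely: the projected image of a geographic
    # rectangle is curvilinear, so corners alone do not bound it.
    t = np.linspace(0.0, 1.0, 101)
    lons = np.concatenate([
        lon_min + t * (lon_max - lon_min),
        np.full_like(t, lon_max),
        lon_max - t * (lon_max - lon_min),
        np.full_like(t, lon_min),
    ])
    lats = np.concatenate([
        np.full_like(t, lat_min),
        lat_min + t * (lat_max - lat_min),
        np.full_like(t, lat_max),
        lat_max - t * (lat_max - lat_min),
    ])
    x, y = proj.forward(lons, lats)
    eps = 1e-9
    n_cols = int(np.ceil((x.max() - x.min()) / cell_size - eps))
    n_rows = int(np.ceil((y.max() - y.min()) / cell_size - eps))
    return GridSpec(
        origin_x=float(x.min()),
        origin_y=float(y.min()),
        cell_size=float(cell_size),
        n_cols=max(n_cols, 1),
        n_rows=max(n_rows, 1),
        projection=proj,
    )


def assign_cells(observations: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Attach a ``cell_id`` column; rows outside the grid get cell_id = -1."""
    out = observations.copy()
    out["cell_id"] = grid.cell_of_lonlat(out["lon"].to_numpy(), out["lat"].to_numpy())
    return out


def assign_and_aggregate(
    observations: pd.DataFrame,
    grid: GridSpec,
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[list[CellSample], dict]:
    """Map observations to grid cells and aggregate per species x year x cell.

    Returns the retained :class:`CellSample` list (n >= min_count) and a
    coverage summary accounting for every input row: retained, sub-threshold
    (cells present but below min_count) and outside-grid counts.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    summary = {
        "n_input": int(len(observations)),
        "n_outside": 0,
        "n_subthreshold": 0,
        "n_retained": 0,
        "subthreshold_cells": [],
    }
    if observations.empty:
        return [], summary
    assigned = assign_cells(observations, grid)
    outside = assigned["cell_id"] < 0
    summary["n_outside"] = int(outside.sum())
    if summary["n_outside"]:
        logger.info("dropped %d observations outside the grid", summary["n_outside"])
    inside = assigned.loc[~outside]
    samples: list[CellSample] = []
    for (species, year, cell_id), group in inside.groupby(
        ["species", "year", "cell_id"], sort=True
    ):
        doys = np.sort(group["doy"].to_numpy())
        if len(doys) >= min_count:
            samples.append(CellSample(str(species), int(year), int(cell_id), doys))
            summary["n_retained"] += len(doys)
        else:
            summary["n_subthreshold"] += len(doys)
            summary["subthreshold_cells"].append((str(species), int(year), int(cell_id), len(doys)))
    return samples, summary


def cell_covariates(
    grid: GridSpec,
    elevation: pd.DataFrame,
    retained_cells=None,
) -> pd.DataFrame:
    """Per-cell covariate table: mean elevation plus centroid lat/lon.

    ``elevation`` is a point table with columns lon, lat, elev (one row per
    source pixel centre); pixels are assigned to cells and averaged. Raises
    if any requested cell has no elevation pixels.
    """
    ids = (
        np.arange(grid.n_cells)
        if retained_cells is None
        else np.unique(np.asarray(retained_cells, int))
    )
    pix = elevation.copy()
    pix["cell_id"] = grid.cell_of_lonlat(pix["lon"].to_numpy(), pix["lat"].to_numpy())
    means = pix[pix["cell_id"] >= 0].groupby("cell_id")["elev"].mean()
    missing = sorted(set(ids.tolist()) - set(means.index.tolist()))
    if missing:
        raise ValueError(f"no elevation pixels for cells: {missing}")
    lon, lat = grid.centroids_lonlat(ids)
    table = pd.DataFrame(
        {
            "cell_id": ids,
            "elev": means.reindex(ids).to_numpy(),
            "lat": lat,
            "lon": lon,
        }
    )
    if not np.isfinite(table["elev"]).all():
        bad = table.loc[~np.isfinite(table["elev"]), "cell_id"].tolist()
        raise ValueError(f"non-finite elevation for cells: {bad}")
    return table
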