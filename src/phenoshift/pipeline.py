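"""End-to-end orchestration: grid -> MOD -> interpolation -> GDD -> inference.

``run_pipeline`` executes the whole analysis on either synthetic inputs
(generated under the configured seed) or observation/temperature files, and
writes every stage product plus a machine-readable run manifest (config
echo, package and library versions, input digests, per-stage counts).
Reruns with the same config and inputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .grids import assign_and_aggregate, build_grid, cell_covariates
from .phenometrics import mod_table, species_median_mod
from .interpolation import train_interpolator, area_of_applicability, fill_grid
from .climate import gdd_series, gdd_at_mod, gdd_shift
from .inference import (
    fit_gradient_model,
    paired_mod_test,
    classify_season,
    seasonal_trend,
    shift_map,
)
from . import synthetic as synth
from . import io as pio

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _synthetic_inputs(cfg: PipelineConfig):
    """Generate the study conditions: landscape, observations, temperatures."""
    scfg = cfg.synthetic
    grid, cov = synth.make_landscape(
        n_cols=scfg.n_cols, n_rows=scfg.n_rows, cell_size=cfg.grid.cell_size,
        sw_corner=cfg.grid.bbox[:2], seed=cfg.seed,
    )
    surface = synth.TrueSurface(**scfg.surface)
    effort = synth.EffortModel(**scfg.effort)
    climate = synth.SyntheticClimate(**scfg.climate)
    medians = synth.make_true_surface(cov, surface)
    obs = synth.sample_observations(
        medians, effort, surface, scfg.years, seed=cfg.seed + 1, grid=grid
    )
    temps = {}
    for i, year in enumerate(scfg.years):
        offset = scfg.warming_offset_first_year if i == 0 else 0.0
        temps[int(year)] = synth.synth_temperature(
            cov, climate, year=int(year), seed=cfg.seed + 100 + i,
            warming_offset=offset,
        )
    truth = dict(obs.truth)
    return grid, cov, obs.frame, temps, truth


def _file_inputs(cfg: PipelineConfig):
    grid = build_grid(cfg.grid.bbox, cfg.grid.cell_size)
    obs, counts = pio.read_observations(list(cfg.paths.observations))
    if cfg.paths.elevation is None:
        raise ValueError("file mode requires an elevation table path")
    elev = pd.read_csv(cfg.paths.elevation)
    cell_ids = np.unique(
        grid.cell_of_lonlat(obs["lon"].to_numpy(), obs["lat"].to_numpy())
    )
    cov = cell_covariates(grid, elev, cell_ids[cell_ids >= 0])
    temps = {
        int(year): pio.read_temperature_grid(path, grid)
        for year, path in cfg.paths.temperature.items()
    }
    return grid, cov, obs, temps, {"read_counts": counts}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write stage outputs under ``config.paths.out_dir``.

    Returns a result bundle with the in-memory tables and the manifest.
    """
    out_dir = Path(config.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "phenoshift",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        if config.mode == "synthetic":
            grid, cov, obs, temps, meta = _synthetic_inputs(config)
        elif config.mode == "files":
            grid, cov, obs, temps, meta = _file_inputs(config)
            manifest["input_digests"] = {
                str(p): _digest(Path(p)) for p in config.paths.observations
            }
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        manifest["stages"]["inputs"] = {
            "n_observations": int(len(obs)),
            "n_cells": int(grid.n_cells),
            **({"truth": meta} if config.mode == "synthetic" else meta),
        }

        samples, coverage = assign_and_aggregate(
            obs, grid, min_count=config.phenometrics.min_count
        )
        coverage.pop("subthreshold_cells", None)
        manifest["stages"]["aggregate"] = coverage

        mod_grid, failures = mod_table(
            samples,
            q=config.phenometrics.q,
            n_bootstrap=config.phenometrics.n_bootstrap,
            seed=config.seed,
            min_count=config.phenometrics.min_count,
        )
        manifest["stages"]["phenometrics"] = {
            "n_estimated": int(len(mod_grid)),
            "n_failed": len(failures),
        }
        mod_grid.to_csv(out_dir / "mod_observed.csv", index=False)

        filled_parts, aoa_parts = [], []
        if config.interpolation.enabled:
            for (species, year), part in mod_grid.groupby(["species", "year"]):
                try:
                    model = train_interpolator(
                        part, cov,
                        param_grid=config.interpolation.param_grid,
                        cv_folds=config.interpolation.cv_folds,
                    )
                except ValueError as exc:
                    logger.info("interpolation skipped for %s %s: %s", species, year, exc)
                    filled_parts.append(part)
                    continue
                aoa = area_of_applicability(model, cov)
                aoa.insert(0, "species", species)
                aoa.insert(1, "year", year)
                aoa_parts.append(aoa)
                filled, _excluded = fill_grid(part, model, aoa, cov, species, year)
                filled_parts.append(filled)
            filled_grid = (
                pd.concat(filled_parts, ignore_index=True) if filled_parts else mod_grid
            )
        else:
            filled_grid = mod_grid.copy()
        filled_grid.to_csv(out_dir / "mod_filled.csv", index=False)
        if aoa_parts:
            pd.concat(aoa_parts, ignore_index=True).to_csv(out_dir / "aoa.csv", index=False)
        manifest["stages"]["interpolation"] = {
            "enabled": config.interpolation.enabled,
            "n_interpolated": int((filled_grid["provenance"] == "interpolated").sum()),
        }

        years = sorted(mod_grid["year"].unique().tolist())
        gdd_tables = {}
        if config.climate.enabled and temps:
            for year in years:
                if int(year) not in temps:
                    continue
                gdd = gdd_series(temps[int(year)], base_temp=config.climate.base_temp)
                part = mod_grid[mod_grid["year"] == year]
                gdd_tables[int(year)] = gdd_at_mod(gdd, part)
            if len(gdd_tables) >= 2:
                y1, y2 = sorted(gdd_tables)[:2]
                per_cell, summary = gdd_shift(gdd_tables[y1], gdd_tables[y2])
                per_cell.to_csv(out_dir / "gdd_shift_cells.csv", index=False)
                summary.to_csv(out_dir / "gdd_shift_species.csv", index=False)
                manifest["stages"]["climate"] = {
                    "years": [y1, y2],
                    "n_shared_cells": int(len(per_cell)),
                }

        fits = []
        for (species, year), part in mod_grid.groupby(["species", "year"]):
            try:
                fit = fit_gradient_model(
                    filled_grid[(filled_grid["species"] == species) & (filled_grid["year"] == year)]
                    if not config.inference.observed_only
                    else part,
                    cov,
                    observed_only=config.inference.observed_only,
                )
            except ValueError as exc:
                logger.info("gradient fit skipped for %s %s: %s", species, year, exc)
                continue
            row = {
                "species": fit.species, "year": fit.year,
                "m_elev_per_km": fit.m_elev_per_km, "m_lat": fit.m_lat,
                "m_lon": fit.m_lon, "intercept": fit.n_intercept,
                "r2": fit.r2, "n_cells": fit.n_cells,
                "residual_sd": fit.residual_sd,
            }
            for k in ("elev", "lat", "lon"):
                row[f"p_raw_{k}"] = fit.p_raw[k]
                row[f"p_adj_{k}"] = fit.p_adj[k]
            fits.append(row)
        fits_df = pd.DataFrame(fits)
        fits_df.to_csv(out_dir / "gradient_fits.csv", index=False)

        medians = species_median_mod(mod_grid)
        medians.to_csv(out_dir / "species_median_mod.csv", index=False)
        ref_year = config.inference.reference_year or (years[0] if years else None)
        results: dict = {
            "grid": grid, "covariates": cov, "mod_grid": mod_grid,
            "filled_grid": filled_grid, "gradient_fits": fits_df,
            "species_medians": medians, "gdd_tables": gdd_tables,
        }
        if ref_year is not None and not medians.empty:
            seasons = classify_season(
                medians, ref_year, threshold_doy=config.inference.season_threshold_doy
            )
            seasons.to_csv(out_dir / "season_classes.csv", index=False)
            results["seasons"] = seasons
        if len(years) >= 2:
            y1, y2 = years[:2]
            m1 = mod_grid[mod_grid["year"] == y1]
            m2 = mod_grid[mod_grid["year"] == y2]
            shifts = shift_map(m1, m2)
            shifts.to_csv(out_dir / "mod_shift_cells.csv", index=False)
            try:
                tests = paired_mod_test(m1, m2)
                tests.to_csv(out_dir / "mod_shift_tests.csv", index=False)
                results["shift_tests"] = tests
            except ValueError as exc:
                logger.info("shift test skipped: %s", exc)
            results["shifts"] = shifts
        # seasonal course of the gradient coefficients (needs >= 4 points)
        if len(fits_df) >= 4 and not medians.empty:
            pts = fits_df.merge(medians, on=["species", "year"])
            trends = [
                seasonal_trend(pts, response)
                for response in ("m_elev_per_km", "m_lat", "m_lon")
            ]
            trends_df = pd.DataFrame(trends)
            trends_df.to_csv(out_dir / "seasonal_trends.csv", index=False)
            results["seasonal_trends"] = trends_df
    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
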