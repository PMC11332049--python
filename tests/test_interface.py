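"""Readers/writers, configuration round-trip, and end-to-end pipeline runs."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from phenoshift import synthetic as synth
from phenoshift.config import PipelineConfig
from phenoshift.io import (
    read_observations,
    write_temperature_netcdf,
    read_temperature_netcdf,
    read_temperature_grid,
)
from phenoshift.pipeline import run_pipeline


def write_obs_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadObservations:
    def test_well_formed_rows(self, tmp_path):
        p = write_obs_csv(tmp_path / "a.csv", {
            "species": ["x", "x", "y"],
            "longitude": [10.0, 11.0, 12.0],
            "latitude": [50.0, 51.0, 52.0],
            "date": ["2020-05-01", "2020-05-02", "2020-06-01"],
        })
        obs, counts = read_observations(p)
        assert len(obs) == 3 and counts["n_dropped"] == 0
        assert obs.loc[0, "doy"] == 122 and obs.loc[0, "year"] == 2020  # May 1, leap year

    def test_invalid_latitude_dropped(self, tmp_path):
        p = write_obs_csv(tmp_path / "a.csv", {
            "species": ["x", "x"], "longitude": [10.0, 10.0],
            "latitude": [95.0, 50.0], "date": ["2020-05-01", "2020-05-01"],
        })
        obs, counts = read_observations(p)
        assert len(obs) == 1 and counts["n_dropped"] == 1

    def test_unparseable_date_dropped(self, tmp_path):
        p = write_obs_csv(tmp_path / "a.csv", {
            "species": ["x", "x"], "longitude": [10.0, 10.0],
            "latitude": [50.0, 50.0], "date": ["not-a-date", "2021-07-01"],
        })
        obs, counts = read_observations(p)
        assert len(obs) == 1 and counts["n_dropped"] == 1

    def test_pooling_conserves_counts(self, tmp_path):
        p1 = write_obs_csv(tmp_path / "a.csv", {
            "species": ["x"] * 4, "longitude": [10.0] * 4, "latitude": [50.0] * 4,
            "date": ["2020-05-01"] * 4,
        })
        p2 = write_obs_csv(tmp_path / "b.csv", {
            "species": ["y"] * 3, "longitude": [11.0] * 3, "latitude": [51.0] * 3,
            "date": ["2021-06-01"] * 3,
        })
        obs, counts = read_observations([p1, p2])
        per_source = sum(v["retained"] for v in counts["per_source"].values())
        assert len(obs) == per_source == 7

    def test_missing_column_named(self, tmp_path):
        p = write_obs_csv(tmp_path / "a.csv", {
            "species": ["x"], "longitude": [10.0], "date": ["2020-05-01"],
        })
        with pytest.raises(ValueError, match="latitude"):
            read_observations(p)

    def test_column_map_override(self, tmp_path):
        p = write_obs_csv(tmp_path / "a.csv", {
            "taxon": ["x"], "x": [10.0], "y": [50.0], "obs_date": ["2020-05-01"],
        })
        obs, _ = read_observations(p, column_map={
            "species": "taxon", "lon": "x", "lat": "y", "date": "obs_date"})
        assert len(obs) == 1


class TestTemperatureIO:
    def test_netcdf_roundtrip(self, tmp_path, flat_grid):
        _, cov = flat_grid
        cube = synth.synth_temperature(cov, synth.SyntheticClimate(), 2020, seed=0)
        path = tmp_path / "t.nc"
        write_temperature_netcdf(cube, path)
        back = read_temperature_netcdf(path)
        assert np.allclose(back["tmin"].values, cube["tmin"].values)
        assert np.allclose(back["tmax"].values, cube["tmax"].values)

    def test_rescale_uniform_source(self, tmp_path, flat_grid):
        grid, _ = flat_grid
        # a fine lat/lon source grid with a constant field
        lats = np.linspace(47.6, 49.6, 40)
        lons = np.linspace(7.6, 10.6, 40)
        time = pd.date_range("2020-01-01", "2020-12-30")  # 365 days
        src = xr.Dataset(
            {"tmin": (("time", "lat", "lon"), np.full((365, 40, 40), 4.0)),
             "tmax": (("time", "lat", "lon"), np.full((365, 40, 40), 12.0))},
            coords={"time": time, "lat": lats, "lon": lons},
        )
        path = tmp_path / "src.nc"
        src.to_netcdf(path, engine="scipy")
        cube = read_temperature_grid(path, grid)
        assert np.allclose(cube["tmin"].values, 4.0)
        assert np.allclose(cube["tmax"].values, 12.0)
        assert cube.sizes["day"] == 365

    def test_leap_year_folded_to_365_days(self, tmp_path, flat_grid):
        """A 366-day source collapses to 365 days with Feb 28/29 averaged."""
        grid, _ = flat_grid
        lats = np.linspace(47.6, 49.6, 10)
        lons = np.linspace(7.6, 10.6, 10)
        time = pd.date_range("2020-01-01", "2020-12-31")  # leap year, 366 d
        vals = np.arange(366, dtype=float)[:, None, None] * np.ones((1, 10, 10))
        src = xr.Dataset(
            {"tmin": (("time", "lat", "lon"), vals),
             "tmax": (("time", "lat", "lon"), vals + 5.0)},
            coords={"time": time, "lat": lats, "lon": lons},
        )
        path = tmp_path / "leap.nc"
        src.to_netcdf(path, engine="scipy")
        cube = read_temperature_grid(path, grid)
        assert cube.sizes["day"] == 365
        # DOY 59 holds the Feb 28/29 average; March 1 becomes DOY 60
        assert np.allclose(cube["tmin"].sel(day=59).values, 0.5 * (58 + 59))
        assert np.allclose(cube["tmin"].sel(day=60).values, 60.0)

    def test_rescale_temporal_gap_errors(self, tmp_path, flat_grid):
        grid, _ = flat_grid
        lats = np.linspace(47.6, 49.6, 10)
        lons = np.linspace(7.6, 10.6, 10)
        time = pd.date_range("2020-01-01", "2020-06-01")  # partial year
        src = xr.Dataset(
            {"tmin": (("time", "lat", "lon"), np.zeros((len(time), 10, 10))),
             "tmax": (("time", "lat", "lon"), np.ones((len(time), 10, 10)))},
            coords={"time": time, "lat": lats, "lon": lons},
        )
        path = tmp_path / "src.nc"
        src.to_netcdf(path, engine="scipy")
        with pytest.raises(ValueError, match="gaps"):
            read_temperature_grid(path, grid)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = PipelineConfig()
        cfg.seed = 7
        cfg.phenometrics.min_count = 20
        path = tmp_path / "c.yaml"
        cfg.to_yaml(path)
        back = PipelineConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_defaults_echoed(self):
        d = PipelineConfig().to_dict()
        assert d["phenometrics"]["min_count"] == 25
        assert d["climate"]["base_temp"] == 5.0
        assert d["grid"]["cell_size"] == 50_000.0


def fast_synthetic_config(out_dir, seed=3):
    cfg = PipelineConfig()
    cfg.seed = seed
    cfg.mode = "synthetic"
    cfg.paths.out_dir = str(out_dir)
    cfg.synthetic.n_cols = 5
    cfg.synthetic.n_rows = 5
    cfg.synthetic.effort = {"n_hotspots": 2, "mean_obs_per_cell": 60.0}
    cfg.phenometrics.n_bootstrap = 100
    return cfg


class TestRunPipeline:
    def test_end_to_end_recovers_gradients(self, tmp_path):
        cfg = fast_synthetic_config(tmp_path / "r1")
        results = run_pipeline(cfg)
        fits = results["gradient_fits"]
        assert len(fits) == 2  # one species, two years
        # default generating surface: 20 d/km, 4 d/deg lat
        assert fits["m_elev_per_km"].mean() == pytest.approx(20.0, abs=4.0)
        assert fits["m_lat"].mean() == pytest.approx(4.0, abs=1.0)
        # the warmer first year plus the year shift both delay year 2
        assert results["shift_tests"]["median_shift"].iloc[0] > 0
        for name in ("mod_observed.csv", "mod_filled.csv", "gradient_fits.csv",
                     "manifest.json"):
            assert (tmp_path / "r1" / name).exists()

    def test_same_seed_identical_digests(self, tmp_path):
        digests = []
        for sub in ("a", "b"):
            cfg = fast_synthetic_config(tmp_path / sub)
            run_pipeline(cfg)
            h = hashlib.sha256()
            for name in sorted(("mod_observed.csv", "mod_filled.csv",
                                "gradient_fits.csv", "mod_shift_cells.csv")):
                h.update((tmp_path / sub / name).read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_interpolation_disabled_no_interpolated_rows(self, tmp_path):
        cfg = fast_synthetic_config(tmp_path / "r2")
        cfg.interpolation.enabled = False
        results = run_pipeline(cfg)
        assert (results["filled_grid"]["provenance"] == "observed").all()
        manifest = json.loads((tmp_path / "r2" / "manifest.json").read_text())
        assert manifest["stages"]["interpolation"]["n_interpolated"] == 0

    def test_file_mode_matches_synthetic_inputs(self, tmp_path, flat_grid):
        """Observations written to CSV and re-read give the same MODs."""
        grid, cov = flat_grid
        surface = synth.TrueSurface(beta_elev=0, beta_lat=0, beta_lon=0,
                                    year_shift=0, dispersion=6.0)
        med = synth.make_true_surface(cov, surface)
        eff = synth.EffortModel(n_hotspots=0, mean_obs_per_cell=80)
        obs = synth.sample_observations(med, eff, surface, [2020], seed=5, grid=grid)
        path = tmp_path / "obs.csv"
        obs.to_csv(path)
        back, _ = read_observations(path)
        assert len(back) == len(obs.frame)
        assert np.array_equal(back["doy"].to_numpy(), obs.frame["doy"].to_numpy())


class TestCLI:
    def test_simulate_and_run(self, tmp_path):
        from click.testing import CliRunner
        from phenoshift.cli import main

        runner = CliRunner()
        out = tmp_path / "obs.csv"
        res = runner.invoke(main, ["simulate", "--seed", "1", "--out", str(out),
                                   "--n-cols", "4", "--n-rows", "4"])
        assert res.exit_code == 0, res.output
        assert out.exists() and out.with_suffix(".truth.json").exists()

        cfg = fast_synthetic_config(tmp_path / "cli_run", seed=2)
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        res = runner.invoke(main, ["run", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "cli_run" / "gradient_fits.csv").exists()
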