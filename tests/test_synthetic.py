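"""Generator contracts: exact surfaces, determinism, distributional medians."""

import io

import numpy as np
import pandas as pd
import pytest

from phenoshift import synthetic as synth


def surface(**kw):
    defaults = dict(beta0=150.0, beta_elev=0.0, beta_lat=0.0, beta_lon=0.0,
                    year_shift=0.0, dispersion=5.0, shape_family="normal")
    defaults.update(kw)
    return synth.TrueSurface(**defaults)


class TestTrueSurface:
    def test_constant_surface(self, flat_grid):
        _, cov = flat_grid
        med = synth.make_true_surface(cov, surface())
        assert np.allclose(med["true_median"], 150.0)

    def test_latitude_gradient_four_days_per_degree(self, flat_grid):
        """One degree of latitude separates medians by exactly 4 days."""
        _, cov = flat_grid
        cov = cov.copy()
        cov["lat"] = [50.0, 51.0, 50.0, 51.0] * 4
        med = synth.make_true_surface(cov, surface(beta_lat=4.0))
        diff = med.loc[cov["lat"] == 51.0, "true_median"].mean() - med.loc[
            cov["lat"] == 50.0, "true_median"].mean()
        assert diff == pytest.approx(4.0)

    def test_elevation_slope(self, flat_grid):
        _, cov = flat_grid
        cov = cov.copy()
        cov["elev"] = 0.0
        cov.loc[0, "elev"] = 500.0
        med = synth.make_true_surface(cov, surface(beta_elev=20.0))
        assert med.loc[0, "true_median"] - med.loc[1, "true_median"] == pytest.approx(10.0)

    def test_clipping_warns(self, flat_grid):
        _, cov = flat_grid
        with pytest.warns(UserWarning, match="clipped"):
            med = synth.make_true_surface(cov, surface(beta0=400.0))
        assert (med["true_median"] <= 365).all()

    def test_missing_covariate_errors(self, flat_grid):
        _, cov = flat_grid
        cov = cov.copy()
        cov.loc[3, "elev"] = np.nan
        with pytest.raises(ValueError, match="3"):
            synth.make_true_surface(cov, surface())


class TestSampleObservations:
    def test_degenerate_dispersion_pins_dates(self, flat_grid):
        grid, cov = flat_grid
        med = synth.make_true_surface(cov, surface(dispersion=0.1))
        obs = synth.sample_observations(
            med.iloc[:1], synth.EffortModel(n_hotspots=0, mean_obs_per_cell=40),
            surface(dispersion=0.1), [2020], seed=3, grid=grid)
        assert (obs.frame["doy"] == 150).all()

    def test_seed_determinism_bytes(self, flat_grid):
        grid, cov = flat_grid
        med = synth.make_true_surface(cov, surface())
        outs = []
        for _ in range(2):
            obs = synth.sample_observations(
                med, synth.EffortModel(), surface(), [2020, 2021], seed=11, grid=grid)
            buf = io.StringIO()
            obs.frame.to_csv(buf, index=False)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_large_sample_median_recovers_truth(self, flat_grid):
        grid, cov = flat_grid
        med = synth.make_true_surface(cov, surface(dispersion=10.0))
        eff = synth.EffortModel(n_hotspots=0, hotspot_concentration=100,
                                mean_obs_per_cell=10_000, count_family="poisson")
        obs = synth.sample_observations(med.iloc[:1], eff, surface(dispersion=10.0),
                                        [2020], seed=5, grid=grid)
        assert np.median(obs.frame["doy"]) == pytest.approx(150.0, abs=0.5)

    def test_year_shift_moves_medians(self, flat_grid):
        grid, cov = flat_grid
        s = surface(year_shift=7.0, dispersion=2.0)
        med = synth.make_true_surface(cov, s)
        eff = synth.EffortModel(n_hotspots=0, hotspot_concentration=100,
                                mean_obs_per_cell=2000, count_family="poisson")
        obs = synth.sample_observations(med, eff, s, [2020, 2021], seed=6, grid=grid)
        by_year = obs.frame.groupby("year")["doy"].median()
        assert by_year[2021] - by_year[2020] == pytest.approx(7.0, abs=0.5)

    def test_weibull_family_median(self, flat_grid):
        grid, cov = flat_grid
        s = surface(shape_family="weibull", dispersion=12.0)
        med = synth.make_true_surface(cov, s)
        eff = synth.EffortModel(n_hotspots=0, hotspot_concentration=100,
                                mean_obs_per_cell=10_000, count_family="poisson")
        obs = synth.sample_observations(med.iloc[:1], eff, s, [2020], seed=9, grid=grid)
        assert np.median(obs.frame["doy"]) == pytest.approx(150.0, abs=1.0)

    def test_points_fall_in_their_cell(self, flat_grid):
        grid, cov = flat_grid
        med = synth.make_true_surface(cov, surface())
        obs = synth.sample_observations(med, synth.EffortModel(), surface(),
                                        [2020], seed=12, grid=grid)
        recovered = grid.cell_of_lonlat(obs.frame["lon"].to_numpy(),
                                        obs.frame["lat"].to_numpy())
        assert (recovered == obs.frame["cell_id"].to_numpy()).all()


class TestSynthTemperature:
    def test_constant_field(self, flat_grid):
        _, cov = flat_grid
        clim = synth.SyntheticClimate(t_mean_annual=10, seasonal_amplitude=0,
                                      lapse_rate=0, lat_gradient=0,
                                      daily_noise_sd=0, diurnal_range=4)
        cube = synth.synth_temperature(cov, clim, 2020, seed=0)
        tmean = (cube["tmin"] + cube["tmax"]) / 2
        assert np.allclose(tmean.values, 10.0)

    def test_lapse_rate_offset(self, flat_grid):
        _, cov = flat_grid
        cov = cov.copy()
        cov["elev"] = 0.0
        cov.loc[1, "elev"] = 1000.0
        clim = synth.SyntheticClimate(lapse_rate=6.5, lat_gradient=0,
                                      daily_noise_sd=0)
        cov["lat"] = 50.0
        cube = synth.synth_temperature(cov, clim, 2020, seed=0)
        tmean = ((cube["tmin"] + cube["tmax"]) / 2).values
        assert np.allclose(tmean[0] - tmean[1], 6.5)

    def test_diurnal_range_exact(self, flat_grid):
        _, cov = flat_grid
        clim = synth.SyntheticClimate(daily_noise_sd=0, diurnal_range=8.0)
        cube = synth.synth_temperature(cov, clim, 2020, seed=0)
        assert np.allclose((cube["tmax"] - cube["tmin"]).values, 8.0)

    def test_seed_determinism(self, flat_grid):
        _, cov = flat_grid
        clim = synth.SyntheticClimate()
        a = synth.synth_temperature(cov, clim, 2020, seed=4)
        b = synth.synth_temperature(cov, clim, 2020, seed=4)
        assert np.array_equal(a["tmin"].values, b["tmin"].values)


class TestGddCoupled:
    def constant_cube(self, cov, tmean, year=2020):
        clim = synth.SyntheticClimate(t_mean_annual=tmean, seasonal_amplitude=0,
                                      lapse_rate=0, lat_gradient=0,
                                      daily_noise_sd=0, diurnal_range=0)
        return synth.synth_temperature(cov, clim, year, seed=0)

    def test_constant_15C_threshold_100_crosses_day_10(self, flat_grid):
        """10 degC/day above base 5: cumulative GDD hits 100 on day 10."""
        grid, cov = flat_grid
        temps = {2020: self.constant_cube(cov, 15.0)}
        _, truth = synth.make_gdd_coupled_observations(
            temps, 100.0, synth.EffortModel(), dispersion=3.0, seed=1, grid=grid)
        assert (truth["crossing_doy"] == 10).all()
        assert (truth["true_median"] == 10).all()

    def test_zero_threshold_first_warm_day(self, flat_grid):
        grid, cov = flat_grid
        temps = {2020: self.constant_cube(cov, 15.0)}
        _, truth = synth.make_gdd_coupled_observations(
            temps, 0.0, synth.EffortModel(), dispersion=3.0, seed=1, grid=grid)
        assert (truth["crossing_doy"] == 1).all()

    def test_unreachable_threshold_errors(self, flat_grid):
        grid, cov = flat_grid
        temps = {2020: self.constant_cube(cov, 4.0)}
        with pytest.raises(ValueError, match="unreachable"):
            synth.make_gdd_coupled_observations(
                temps, 100.0, synth.EffortModel(), dispersion=3.0, seed=1, grid=grid)

    def test_identical_years_no_shift(self, flat_grid):
        grid, cov = flat_grid
        temps = {2020: self.constant_cube(cov, 15.0),
                 2021: self.constant_cube(cov, 15.0, 2021)}
        _, truth = synth.make_gdd_coupled_observations(
            temps, 100.0, synth.EffortModel(), dispersion=3.0, seed=1, grid=grid)
        piv = truth.pivot(index="cell_id", columns="year", values="true_median")
        assert np.allclose(piv[2020], piv[2021])


def test_observation_set_csv_roundtrip(tmp_path, flat_grid):
    grid, cov = flat_grid
    med = synth.make_true_surface(cov, surface())
    obs = synth.sample_observations(med, synth.EffortModel(), surface(),
                                    [2020], seed=2, grid=grid)
    path = tmp_path / "obs.csv"
    obs.to_csv(path)
    back = pd.read_csv(path)
    assert list(back.columns) == ["species", "longitude", "latitude", "date"]
    assert len(back) == len(obs.frame)
    assert (tmp_path / "obs.truth.json").exists()
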