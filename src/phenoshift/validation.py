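"""Desk-scale simulation studies validating each pipeline stage.

These harnesses run the package on synthetic data with known ground truth
and measure recovery: the latitudinal gradient (the classical four days per
degree of latitude), the small-sample calibration of the bias-corrected
Weibull median, the complementary-sign relationship between MOD shifts and
GDD shifts under a uniformly warmer year, the type-I error of the paired
Wilcoxon shift test, and coverage of the gradient-regression CIs. Both the
test suite and ``scripts/acceptance.py`` call them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import assign_and_aggregate
from .phenometrics import _fit_shapes_vectorized, mod_table
from .climate import gdd_series, gdd_at_mod, gdd_shift
from .inference import fit_gradient_model, shift_map
from . import synthetic as synth

#: Study conditions for gradient-recovery runs: a 100-cell landscape with
#: ample, near-uniform effort (>=100 observations in nearly every cell).
RECOVERY_SURFACE = synth.TrueSurface(
    beta0=150.0, beta_elev=20.0, beta_lat=4.0, beta_lon=0.5,
    year_shift=7.0, dispersion=10.0, shape_family="normal",
)
RECOVERY_EFFORT = synth.EffortModel(
    n_hotspots=0, hotspot_concentration=50.0, mean_obs_per_cell=150.0,
    count_family="poisson",
)


def _weibull_true_quantile(shape: float, scale: float, q: float = 0.5) -> float:
    return scale * (-np.log1p(-q)) ** (1.0 / shape)


def mod_calibration(
    seed: int,
    n: int = 25,
    n_replicates: int = 500,
    n_bootstrap: int = 100,
    shape: float = 2.0,
    scale: float = 160.0,
) -> dict:
    """Small-sample calibration of the bias-corrected Weibull median.

    Draws ``n_replicates`` samples of size ``n`` (antithetic pairs, a
    variance-reduction design so the mean bias is measured rather than
    Monte-Carlo noise), estimates the median naively (MLE plug-in) and with
    the parametric-bootstrap correction, and returns the mean bias and mean
    absolute error of both against the closed-form true median.
    """
    rng = np.random.default_rng(seed)
    true_median = _weibull_true_quantile(shape, scale)
    half = n_replicates // 2
    u = rng.random((half, n))
    u = np.vstack([u, 1.0 - u])[:n_replicates]
    x = scale * (-np.log1p(-u)) ** (1.0 / shape)
    k_hat, s_hat = _fit_shapes_vectorized(x)
    naive = s_hat * np.log(2.0) ** (1.0 / k_hat)
    # parametric bootstrap per replicate, flattened into one vectorized fit
    reps = len(x)
    ub = rng.random((reps, n_bootstrap, n))
    boot = s_hat[:, None, None] * (-np.log1p(-ub)) ** (1.0 / k_hat[:, None, None])
    k_b, s_b = _fit_shapes_vectorized(boot.reshape(reps * n_bootstrap, n))
    theta_b = (s_b * np.log(2.0) ** (1.0 / k_b)).reshape(reps, n_bootstrap)
    corrected = naive - (theta_b.mean(axis=1) - naive)
    return {
        "true_median": float(true_median),
        "n": n,
        "n_replicates": reps,
        "naive_bias": float(naive.mean() - true_median),
        "corrected_bias": float(corrected.mean() - true_median),
        "naive_abs_bias": float(abs(naive.mean() - true_median)),
        "corrected_abs_bias": float(abs(corrected.mean() - true_median)),
        "naive_mae": float(np.abs(naive - true_median).mean()),
        "corrected_mae": float(np.abs(corrected - true_median).mean()),
    }


def large_n_median_agreement(
    seed: int, n: int = 10_000, shape: float = 5.0, scale: float = 160.0
) -> dict:
    """Corrected median vs truth and the empirical sample median at large n."""
    from .phenometrics import estimate_percentile

    rng = np.random.default_rng(seed)
    x = scale * rng.weibull(shape, n)
    est = estimate_percentile(x, n_bootstrap=100, seed=seed + 1)
    true_median = _weibull_true_quantile(shape, scale)
    return {
        "corrected": est.mod,
        "true_median": float(true_median),
        "empirical_median": float(np.median(x)),
        "abs_error_vs_true": float(abs(est.mod - true_median)),
        "abs_error_vs_empirical": float(abs(est.mod - np.median(x))),
    }


def run_gradient_recovery(
    seed: int,
    n_cols: int = 10,
    n_rows: int = 10,
    surface: synth.TrueSurface = RECOVERY_SURFACE,
    effort: synth.EffortModel = RECOVERY_EFFORT,
    n_bootstrap: int = 100,
    min_count: int = 25,
):
    """One gradient-recovery replicate: generate -> grid -> MOD -> OLS.

    Returns the GradientFit for a single synthetic species-year on a
    landscape of ``n_cols x n_rows`` 50-km cells (100 cells by default,
    spanning ~4.5 degrees of latitude).
    """
    grid, cov = synth.make_landscape(n_cols=n_cols, n_rows=n_rows, seed=seed)
    medians = synth.make_true_surface(cov, surface)
    obs = synth.sample_observations(
        medians, effort, surface, [2020], seed=seed + 1, grid=grid
    )
    samples, _ = assign_and_aggregate(obs.frame, grid, min_count=min_count)
    mod_grid, _ = mod_table(samples, n_bootstrap=n_bootstrap, seed=seed + 2,
                            min_count=min_count)
    return fit_gradient_model(mod_grid, cov)


def hopkins_recovery(seed: int, n_seeds: int = 20, **kwargs) -> pd.DataFrame:
    """Recover the latitudinal gradient over ``n_seeds`` replicates.

    The generating surface uses 4 days per degree latitude; returns one row
    per replicate with the recovered coefficients.
    """
    rows = []
    for i in range(n_seeds):
        fit = run_gradient_recovery(seed + 1000 * i, **kwargs)
        rows.append(
            {
                "replicate": i,
                "m_lat": fit.m_lat,
                "m_elev_per_km": fit.m_elev_per_km,
                "m_lon": fit.m_lon,
                "n_cells": fit.n_cells,
            }
        )
    return pd.DataFrame(rows)


def gradient_ci_coverage(
    seed: int,
    n_replicates: int = 100,
    surface: synth.TrueSurface = RECOVERY_SURFACE,
    **kwargs,
) -> dict:
    """Fraction of replicates whose OLS 95% CI covers each true coefficient."""
    true = {"elev": surface.beta_elev / 1000.0, "lat": surface.beta_lat,
            "lon": surface.beta_lon}
    hits = {k: 0 for k in true}
    for i in range(n_replicates):
        fit = run_gradient_recovery(seed + 777 * i, surface=surface, **kwargs)
        for k, v in true.items():
            lo, hi = fit.conf_int[k]
            hits[k] += int(lo <= v <= hi)
    return {k: hits[k] / n_replicates for k in true}


def gdd_sign_contract(
    seed: int,
    n_replicates: int = 50,
    n_cols: int = 10,
    n_rows: int = 10,
    warming: float = 2.0,
    gdd_threshold: float = 200.0,
    dispersion: float = 8.0,
    tracking: float = 0.5,
    n_bootstrap: int = 100,
    min_count: int = 25,
) -> dict:
    """Complementary signs of MOD and GDD shifts under a warmer first year.

    Each replicate builds two climate years (the first uniformly warmer by
    ``warming`` degC), couples flowering to thermal time with partial
    tracking, runs the estimation pipeline, and records the sign of the
    per-species median MOD shift (year2 - year1, expected positive: earlier
    flowering in the warm year) and of the median GDD-at-MOD shift (expected
    negative). Returns the fraction of replicates with the complementary
    sign pattern.
    """
    effort = synth.EffortModel(
        n_hotspots=0, hotspot_concentration=20.0, mean_obs_per_cell=60.0,
        count_family="poisson",
    )
    climate = synth.SyntheticClimate()
    ok = 0
    med_mod_shifts, med_gdd_shifts = [], []
    for i in range(n_replicates):
        rep_seed = seed + 10_000 * i
        grid, cov = synth.make_landscape(n_cols=n_cols, n_rows=n_rows, seed=rep_seed)
        temps = {
            2020: synth.synth_temperature(cov, climate, 2020, seed=rep_seed + 1,
                                          warming_offset=warming),
            2021: synth.synth_temperature(cov, climate, 2021, seed=rep_seed + 2),
        }
        obs, _truth = synth.make_gdd_coupled_observations(
            temps, gdd_threshold, effort, dispersion, seed=rep_seed + 3,
            grid=grid, tracking=tracking,
        )
        samples, _ = assign_and_aggregate(obs.frame, grid, min_count=min_count)
        mod_grid, _ = mod_table(samples, n_bootstrap=n_bootstrap,
                                seed=rep_seed + 4, min_count=min_count)
        m1 = mod_grid[mod_grid["year"] == 2020]
        m2 = mod_grid[mod_grid["year"] == 2021]
        if m1.empty or m2.empty:
            continue
        shifts = shift_map(m1, m2)
        g1 = gdd_at_mod(gdd_series(temps[2020]), m1)
        g2 = gdd_at_mod(gdd_series(temps[2021]), m2)
        _, summary = gdd_shift(g1, g2)
        mod_shift = float(shifts["delta_mod"].median())
        gshift = float(summary["median_delta_gdd"].iloc[0])
        med_mod_shifts.append(mod_shift)
        med_gdd_shifts.append(gshift)
        ok += int(np.sign(mod_shift) == -np.sign(gshift) and mod_shift != 0)
    return {
        "fraction_complementary": ok / n_replicates,
        "n_replicates": n_replicates,
        "median_mod_shift": float(np.median(med_mod_shifts)),
        "median_gdd_shift": float(np.median(med_gdd_shifts)),
    }


def wilcoxon_type1_error(
    seed: int,
    n_sim: int = 1000,
    n_cells: int = 30,
    noise_sd: float = 5.0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the paired shift test under a zero true shift."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        d = rng.normal(0.0, noise_sd, n_cells)
        _, p = stats.wilcoxon(d, alternative="two-sided")
        rejections += int(p < alpha)
    return {"rejection_rate": rejections / n_sim, "n_sim": n_sim, "alpha": alpha}
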