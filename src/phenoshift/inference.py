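"""Bioclimatic gradient regressions and inter-annual shift tests.

The gradient model regresses cell-level median observation dates on
elevation, latitude and longitude:

    MOD = m_elev * elev + m_lat * lat + m_lon * lon + n + eps

(ordinary least squares, one model per species and year). Coefficient
p-values are Holm-adjusted within each model. Inter-annual shifts are
tested per species with a paired two-sided Wilcoxon signed-rank test on
cells estimated in both years, species are classified spring/summer by
their reference-year median MOD against DOY 172, and the seasonal course of
each gradient coefficient is summarised by a quadratic fit against median
MOD (the hump-shaped pattern: gradients peak around the spring-summer
transition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SUMMER_ONSET_DOY = 172


@dataclass(frozen=True)
class GradientFit:
    species: str | None
    year: int | None
    m_elev: float  # days per metre
    m_lat: float  # days per degree latitude
    m_lon: float  # days per degree longitude
    n_intercept: float
    p_raw: dict
    p_adj: dict
    conf_int: dict  # 95% CI per coefficient
    r2: float
    n_cells: int
    residual_sd: float

    @property
    def m_elev_per_km(self) -> float:
        """Elevation coefficient in days per 1000 m."""
        return self.m_elev * 1000.0


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity with a running maximum, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fit_gradient_model(
    mod_grid: pd.DataFrame,
    covariates: pd.DataFrame,
    observed_only: bool = True,
    min_cells: int = 6,
) -> GradientFit:
    """OLS fit of MOD on elevation (m), latitude and longitude (degrees).

    By default only directly observed cells enter the regression:
    interpolated MODs are themselves functions of these covariates and would
    bias the coefficients toward the interpolator. Holm adjustment is
    applied across the three slope p-values of the model.
    """
    data = mod_grid
    if observed_only and "provenance" in data:
        data = data[data["provenance"] == "observed"]
    data = data.merge(covariates, on="cell_id", how="inner")
    if len(data) < min_cells:
        raise ValueError(f"only {len(data)} cells; need >= {min_cells} for the regression")
    X = data[["elev", "lat", "lon"]].to_numpy(dtype=float)
    # collinearity guard: standardized design condition number
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    cond = np.linalg.cond(Z)
    if cond > 1e8:
        corr = np.corrcoef(Z, rowvar=False)
        pairs = [
            (a, b)
            for i, a in enumerate(["elev", "lat", "lon"])
            for j, b in enumerate(["elev", "lat", "lon"])
            if i < j and abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {pairs or 'unknown'}")
    design = sm.add_constant(pd.DataFrame(X, columns=["elev", "lat", "lon"]))
    res = sm.OLS(data["mod"].to_numpy(dtype=float), design).fit()
    slopes = ["elev", "lat", "lon"]
    p_raw = {k: float(res.pvalues[k]) for k in slopes}
    adj = holm_adjust([p_raw[k] for k in slopes])
    ci = res.conf_int()
    return GradientFit(
        species=data["species"].iloc[0] if "species" in data else None,
        year=int(data["year"].iloc[0]) if "year" in data else None,
        m_elev=float(res.params["elev"]),
        m_lat=float(res.params["lat"]),
        m_lon=float(res.params["lon"]),
        n_intercept=float(res.params["const"]),
        p_raw=p_raw,
        p_adj={k: float(v) for k, v in zip(slopes, adj)},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in slopes},
        r2=float(res.rsquared),
        n_cells=int(len(data)),
        residual_sd=float(np.sqrt(res.mse_resid)),
    )


def shift_map(mod_year1: pd.DataFrame, mod_year2: pd.DataFrame) -> pd.DataFrame:
    """Per-cell MOD shift (year2 - year1) on the shared cell set.

    With year1 = 2020 and year2 = 2021, a positive shift means flowering was
    earlier in 2020.
    """
    merged = mod_year1.merge(
        mod_year2, on=["species", "cell_id"], suffixes=("_1", "_2"), how="inner"
    )
    merged["delta_mod"] = merged["mod_2"] - merged["mod_1"]
    return merged[["species", "cell_id", "mod_1", "mod_2", "delta_mod"]]


def paired_mod_test(
    mod_year1: pd.DataFrame, mod_year2: pd.DataFrame, min_cells: int = 6
) -> pd.DataFrame:
    """Paired two-sided Wilcoxon signed-rank test of the per-species shift.

    Pairs are grid cells with a MOD in both years; the reported median shift
    uses the year2 - year1 convention. All-zero differences give p = 1 with
    a degenerate flag.
    """
    shifts = shift_map(mod_year1, mod_year2)
    rows = []
    for species, grp in shifts.groupby("species"):
        d = grp["delta_mod"].to_numpy()
        if len(d) < min_cells:
            raise ValueError(f"{species}: only {len(d)} shared cells; need >= {min_cells}")
        degenerate = bool(np.all(d == 0))
        if degenerate:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(d, alternative="two-sided")
        rows.append(
            {
                "species": species,
                "n_cells": len(d),
                "median_shift": float(np.median(d)),
                "statistic": float(stat),
                "p_value": float(p),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def classify_season(
    species_medians: pd.DataFrame,
    reference_year: int,
    threshold_doy: float = SUMMER_ONSET_DOY,
) -> pd.DataFrame:
    """Spring/summer classification by reference-year median MOD.

    Strictly before DOY 172 is spring-flowering; at or after is
    summer-flowering.
    """
    ref = species_medians[species_medians["year"] == reference_year]
    out = ref[["species", "median_mod"]].copy()
    out["threshold_doy"] = threshold_doy
    out["season"] = np.where(out["median_mod"] < threshold_doy, "spring", "summer")
    return out.reset_index(drop=True)


def seasonal_trend(points: pd.DataFrame, response: str, x: str = "median_mod") -> dict:
    """Quadratic OLS of a gradient coefficient against species median MOD.

    Captures the hump-shaped seasonal course of the bioclimatic gradients.
    Returns coefficients, the vertex location, concavity sign, and the
    quadratic term's p-value. Requires >= 4 points.
    """
    data = points.dropna(subset=[response, x])
    if len(data) < 4:
        raise ValueError(f"need >= 4 points for a quadratic fit, got {len(data)}")
    xv = data[x].to_numpy(dtype=float)
    design = sm.add_constant(np.column_stack([xv, xv**2]))
    res = sm.OLS(data[response].to_numpy(dtype=float), design).fit()
    c0, c1, c2 = res.params
    vertex = float(-c1 / (2 * c2)) if c2 != 0 else np.nan
    return {
        "response": response,
        "intercept": float(c0),
        "linear": float(c1),
        "quadratic": float(c2),
        "vertex_x": vertex,
        "concavity": "down" if c2 < 0 else ("up" if c2 > 0 else "flat"),
        "p_quadratic": float(res.pvalues[2]),
        "r2": float(res.rsquared),
        "n_points": int(len(data)),
    }
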