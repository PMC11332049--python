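"""Spatial interpolation of MOD surfaces with an area of applicability.

Cells with too few observations for direct estimation are filled by
support-vector regression (RBF kernel) on standardized elevation, latitude
and longitude, trained on the directly estimated cells. Predictions are
restricted to the area of applicability (AOA): the region of predictor
space close enough to the training cloud that the model can be trusted.

The AOA follows the dissimilarity-index construction: a target cell's index
is its minimum standardized Euclidean distance to any training cell, scaled
by the mean pairwise distance within the training set; the threshold is the
upper whisker (75th percentile + 1.5 IQR) of the training cells'
leave-one-out indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

PREDICTORS = ("elev", "lat", "lon")

DEFAULT_PARAM_GRID = {
    "C": [10.0, 100.0, 1000.0, 10_000.0],
    "epsilon": [0.1, 0.5],
    "gamma": ["scale", 0.1, 0.01],
}

MIN_TRAINING_CELLS = 10


@dataclass
class InterpolationModel:
    svr: SVR
    mean: np.ndarray
    sd: np.ndarray
    training_cells: np.ndarray
    training_z: np.ndarray
    hyperparams: dict
    training_r2: float
    predictor_names: tuple = PREDICTORS

    def standardize(self, covariates: pd.DataFrame) -> np.ndarray:
        X = covariates.loc[:, list(PREDICTORS)].to_numpy(dtype=float)
        return (X - self.mean) / self.sd

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.svr.predict(self.standardize(covariates))


def train_interpolator(
    mod_grid: pd.DataFrame,
    covariates: pd.DataFrame,
    param_grid: dict | None = None,
    cv_folds: int = 5,
) -> InterpolationModel:
    """Fit an RBF-SVR predicting MOD from standardized (elev, lat, lon).

    Hyperparameters are chosen by k-fold cross-validation over a small fixed
    grid; with deterministic (unshuffled) folds the whole fit is
    deterministic. Requires at least 10 observed cells.
    """
    train = mod_grid.merge(covariates, on="cell_id", how="inner")
    if len(train) < MIN_TRAINING_CELLS:
        raise ValueError(
            f"only {len(train)} observed cells; need >= {MIN_TRAINING_CELLS} to interpolate"
        )
    X = train.loc[:, list(PREDICTORS)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariates in training cells")
    y = train["mod"].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    grid = dict(param_grid or DEFAULT_PARAM_GRID)
    n_folds = min(cv_folds, len(train))
    search = GridSearchCV(
        SVR(kernel="rbf"),
        grid,
        cv=KFold(n_splits=n_folds, shuffle=False),
        scoring="neg_mean_squared_error",
    )
    search.fit(Z, y)
    svr = search.best_estimator_
    r2 = float(svr.score(Z, y)) if np.ptp(y) > 0 else 1.0
    return InterpolationModel(
        svr=svr,
        mean=mean,
        sd=sd,
        training_cells=train["cell_id"].to_numpy(),
        training_z=Z,
        hyperparams=dict(search.best_params_),
        training_r2=r2,
    )


def area_of_applicability(
    model: InterpolationModel,
    covariates: pd.DataFrame,
    target_cells=None,
    normalizer: float | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Dissimilarity index and inside/outside flag per target cell.

    Returns a table (cell_id, dissimilarity_index, normalizer, threshold,
    inside). A target identical in predictor space to a training cell has
    index 0 and is always inside. ``normalizer`` and ``threshold`` default to
    the training-derived values (mean pairwise distance; LOO whisker) but can
    be pinned, e.g. to compare AOAs of nested training sets under one rule.
    """
    targets = covariates if target_cells is None else covariates[
        covariates["cell_id"].isin(np.asarray(target_cells))
    ]
    Zt = model.standardize(targets)
    Ztr = model.training_z
    if normalizer is None:
        normalizer = float(pdist(Ztr).mean())
        if normalizer == 0:
            normalizer = 1.0  # degenerate: all training cells identical
    d = cdist(Zt, Ztr)
    di = d.min(axis=1) / normalizer
    if threshold is None:
        # leave-one-out indices of the training cells define the threshold
        dtr = cdist(Ztr, Ztr)
        np.fill_diagonal(dtr, np.inf)
        loo = dtr.min(axis=1) / normalizer
        q25, q75 = np.percentile(loo, [25, 75])
        threshold = float(q75 + 1.5 * (q75 - q25))
    return pd.DataFrame(
        {
            "cell_id": targets["cell_id"].to_numpy(),
            "dissimilarity_index": di,
            "normalizer": normalizer,
            "threshold": threshold,
            "inside": di <= threshold,
        }
    )


def fill_grid(
    mod_grid: pd.DataFrame,
    model: InterpolationModel,
    aoa: pd.DataFrame,
    covariates: pd.DataFrame,
    species: str | None = None,
    year: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add interpolated MODs for unobserved cells inside the AOA.

    Observed rows pass through untouched; cells outside the AOA are excluded
    and reported. Returns (filled grid, exclusion report).
    """
    observed_ids = set(mod_grid["cell_id"].tolist())
    candidates = aoa[~aoa["cell_id"].isin(observed_ids)]
    inside = candidates[candidates["inside"]]
    excluded = candidates.loc[~candidates["inside"], ["cell_id", "dissimilarity_index", "threshold"]].copy()
    excluded["reason"] = "outside_aoa"
    if inside.empty:
        return mod_grid.copy(), excluded
    cov = covariates.set_index("cell_id").loc[inside["cell_id"]].reset_index()
    preds = model.predict(cov)
    if species is None and not mod_grid.empty:
        species = mod_grid["species"].iloc[0]
    if year is None and not mod_grid.empty:
        year = mod_grid["year"].iloc[0]
    new_rows = pd.DataFrame(
        {
            "species": species,
            "year": year,
            "cell_id": cov["cell_id"].to_numpy(),
            "n": 0,
            "mod": preds,
            "mod_naive": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "provenance": "interpolated",
        }
    )
    filled = pd.concat([mod_grid, new_rows], ignore_index=True)
    return filled, excluded
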