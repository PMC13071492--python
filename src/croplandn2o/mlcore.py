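"""Regression model fitting, selection and interrogation.

Three model families are supported — an identity-link Gaussian linear
model, a random forest and stochastic gradient boosted regression
trees — each tuned by k-fold cross-validation on the development set
(hyperparameters chosen by minimum mean fold RMSE) and compared on an
independent test set by R2, RMSE and MAE.  Fitted models expose
relative variable influence and LOESS-smoothed partial dependence
curves, the standard diagnostics for boosted-tree flux models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, ParameterGrid
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigError, InputError, NotFittedError, SchemaError
from .schema import PREDICTORS, design_matrix

logger = logging.getLogger(__name__)

FAMILIES = ("generalized_linear", "random_forest", "boosted_trees")

#: Default hyperparameter grids (overridable per ModelSpec).  Boosted
#: trees use early stopping on an internal validation split to choose
#: the tree count within each candidate.
DEFAULT_GRIDS = {
    "boosted_trees": {
        "learning_rate": [0.01, 0.05, 0.1],
        "max_depth": [2, 3, 5],
        "subsample": [0.5, 0.75],
    },
    "random_forest": {
        "max_features": [0.33, 0.6, 1.0],
    },
    "generalized_linear": {
        "alpha": [1e-8, 1.0, 10.0],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: dict | None = None
    cv_folds: int = 10
    seed: int = 0
    n_estimators: int = 500

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
        if not grid:
            raise ConfigError("hyperparameter grid must be non-empty")

    @property
    def param_grid(self) -> list[dict]:
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
        return sorted(ParameterGrid(grid), key=lambda d: sorted(d.items()))


@dataclass
class FittedModel:
    """A trained flux regressor with a pure prediction contract."""

    family: str
    hyperparams: dict
    estimator: object
    predictors: tuple[str, ...] = PREDICTORS
    seed: int = 0
    cv_rmse: float = float("nan")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predict net flux (kg N2O-N/ha) for predictor rows; row-order
        independent and deterministic after fit."""
        if self.estimator is None:
            raise NotFittedError("model has not been fitted")
        X = design_matrix(table)
        return np.asarray(self.estimator.predict(X.to_numpy()), dtype=float)


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    mae: float
    n_test: int
    pearson_r2: float = float("nan")

    def __post_init__(self):
        if self.rmse + 1e-12 < self.mae:
            raise ValueError("RMSE cannot be smaller than MAE")


@dataclass
class PDPCurve:
    variable: str
    grid: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    loess_span: float
    extrapolated: bool = False

    @property
    def is_flat(self) -> bool:
        return float(self.raw.max() - self.raw.min()) < 1e-8


def _make_estimator(family: str, params: dict, seed: int, n_estimators: int):
    if family == "boosted_trees":
        return GradientBoostingRegressor(
            n_estimators=n_estimators, random_state=seed,
            n_iter_no_change=10, validation_fraction=0.1, **params)
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **params)
    if family == "generalized_linear":
        return Ridge(random_state=seed, **params)
    raise ConfigError(f"unknown model family {family!r}")


def tune_and_fit(dev: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Grid-search hyperparameters by k-fold CV on the development set,
    then refit the winning configuration on the full development set.

    Fold assignment is seed-deterministic; candidates are scored by
    mean fold RMSE, ties broken by grid order.
    """
    spec.validate()
    if "net_flux" not in dev.columns:
        raise SchemaError("development table must carry a net_flux column")
    if len(dev) <= spec.cv_folds:
        raise ConfigError("development set must be larger than cv_folds")
    X = design_matrix(dev).to_numpy()
    y = dev["net_flux"].to_numpy(float)

    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(X))
    best_params, best_rmse = None, np.inf
    for params in spec.param_grid:
        fold_rmse = []
        for tr, va in folds:
            est = _make_estimator(spec.family, params, spec.seed, spec.n_estimators)
            est.fit(X[tr], y[tr])
            resid = est.predict(X[va]) - y[va]
            fold_rmse.append(float(np.sqrt(np.mean(resid ** 2))))
        mean_rmse = float(np.mean(fold_rmse))
        if not np.isfinite(mean_rmse):
            raise RuntimeError(f"non-finite CV loss for parameters {params}")
        logger.debug("%s %s mean CV RMSE %.4f", spec.family, params, mean_rmse)
        if mean_rmse < best_rmse:
            best_params, best_rmse = params, mean_rmse

    est = _make_estimator(spec.family, best_params, spec.seed, spec.n_estimators)
    est.fit(X, y)
    logger.info("fitted %s with %s (CV RMSE %.4f)", spec.family, best_params, best_rmse)
    return FittedModel(family=spec.family, hyperparams=dict(best_params),
                       estimator=est, seed=spec.seed, cv_rmse=best_rmse)


def evaluate(model: FittedModel, test: pd.DataFrame) -> Metrics:
    """Score predictions on an independent test set.

    R2 is the coefficient of determination on the 1:1 line
    (1 - SSres/SStot); the squared Pearson correlation is reported
    alongside as ``pearson_r2``.
    """
    if len(test) < 2:
        raise InputError("test set must have at least 2 rows")
    y = test["net_flux"].to_numpy(float)
    if np.var(y) == 0:
        raise InputError("R2 undefined on a zero-variance test set")
    pred = model.predict(test)
    resid = pred - y
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    if np.var(pred) > 0:
        pearson = float(np.corrcoef(y, pred)[0, 1] ** 2)
    else:
        pearson = float("nan")
    return Metrics(r2=1.0 - ss_res / ss_tot, rmse=rmse, mae=mae,
                   n_test=len(test), pearson_r2=pearson)


def select_best(candidates: list[tuple[FittedModel, Metrics]]) -> FittedModel:
    """Rank candidates by R2 (desc), then RMSE, MAE (asc), then the
    declared family order; return the winner."""
    if not candidates:
        raise InputError("select_best requires at least one candidate")
    def key(cm):
        model, m = cm
        return (-m.r2, m.rmse, m.mae, FAMILIES.index(model.family))
    ranked = sorted(candidates, key=key)
    for rank, (model, m) in enumerate(ranked, 1):
        logger.info("model ranking %d: %s r2=%.3f rmse=%.3f mae=%.3f",
                    rank, model.family, m.r2, m.rmse, m.mae)
    return ranked[0][0]


def relative_importance(model: FittedModel, table: pd.DataFrame | None = None,
                        seed: int = 0) -> pd.Series:
    """Relative influence of each predictor, in percent (sums to 100).

    Tree families report native impurity-based influence; other
    families fall back to seed-controlled permutation importance,
    which requires a background table with net_flux.
    """
    if model.estimator is None:
        raise NotFittedError("model has not been fitted")
    if hasattr(model.estimator, "feature_importances_"):
        raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    else:
        if table is None:
            raise InputError("permutation importance requires a background table")
        X = design_matrix(table).to_numpy()
        y = table["net_flux"].to_numpy(float)
        res = permutation_importance(model.estimator, X, y, n_repeats=10,
                                     random_state=seed)
        raw = np.clip(res.importances_mean, 0.0, None)
    total = raw.sum()
    pct = raw / total * 100.0 if total > 0 else np.full_like(raw, 100.0 / len(raw))
    return pd.Series(pct, index=list(model.predictors), name="relative_influence_pct")


def partial_dependence(model: FittedModel, background: pd.DataFrame,
                       variable: str, grid: np.ndarray | None = None,
                       loess_span: float = 0.75, n_grid: int = 40,
                       max_background: int = 5000, seed: int = 0) -> PDPCurve:
    """LOESS-smoothed partial dependence of the model on one variable.

    The raw value at g is the mean prediction over the background rows
    with the variable set to g; the background is the development
    table, subsampled with a fixed seed above ``max_background`` rows.
    Grid points outside the observed range trigger a warning and set
    the extrapolation flag.
    """
    if variable not in model.predictors:
        raise InputError(f"{variable!r} is not one of the 12 predictors")
    bg = background
    if len(bg) > max_background:
        bg = bg.sample(max_background, random_state=seed)
    lo = bg[variable].min() if variable != "crop" else 0.0
    hi = bg[variable].max() if variable != "crop" else 1.0
    if grid is None:
        grid = np.linspace(lo, hi, 2 if variable == "crop" else n_grid)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise InputError("evaluation grid must be strictly increasing")
    extrapolated = bool(grid.min() < float(lo) - 1e-12 or grid.max() > float(hi) + 1e-12)
    if extrapolated:
        warnings.warn(f"PDP grid for {variable} extends beyond the training range",
                      stacklevel=2)
    raw = np.empty(grid.shape)
    work = bg.copy()
    for i, g in enumerate(grid):
        work[variable] = g
        raw[i] = float(model.predict(work).mean())
    if len(grid) >= 4:
        smoothed = lowess(raw, grid, frac=loess_span, return_sorted=False)
    else:
        smoothed = raw.copy()
    return PDPCurve(variable=variable, grid=grid, raw=raw,
                    smoothed=np.asarray(smoothed), loess_span=loess_span,
                    extrapolated=extrapolated)
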