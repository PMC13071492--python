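import numpy as np
import pandas as pd
import pytest

from croplandn2o import obsdata, synthgen
from croplandn2o.mlcore import FittedModel
from croplandn2o.schema import PREDICTORS


class _LinearEstimator:
    """Deterministic linear predictor over the canonical design matrix."""

    def __init__(self, coefs, intercept=0.0):
        self.w = np.array([coefs.get(p, 0.0) for p in PREDICTORS], dtype=float)
        self.b = float(intercept)

    def predict(self, X):
        return np.asarray(X) @ self.w + self.b


class _FuncEstimator:
    """Predictor defined by an arbitrary function of the design matrix."""

    def __init__(self, func):
        self.func = func

    def predict(self, X):
        X = np.asarray(X)
        cols = {p: X[:, i] for i, p in enumerate(PREDICTORS)}
        return np.asarray(self.func(cols), dtype=float)


def make_linear_model(coefs, intercept=0.0) -> FittedModel:
    return FittedModel(family="generalized_linear", hyperparams={},
                       estimator=_LinearEstimator(coefs, intercept))


def make_func_model(func) -> FittedModel:
    return FittedModel(family="generalized_linear", hyperparams={},
                       estimator=_FuncEstimator(func))


@pytest.fixture(scope="session")
def noiseless_config():
    return synthgen.default_config(
        noise_params=synthgen.NoiseParams(0.0, 0.0))


@pytest.fixture(scope="session")
def obs_table():
    table, truth = synthgen.generate_observation_table(n=400, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def features_table(obs_table):
    table, _ = obs_table
    screened, _ = obsdata.screen_records(table)
    return obsdata.derive_features(screened)


@pytest.fixture(scope="session")
def small_grid():
    return synthgen.generate_covariate_grid(n_rows=6, n_cols=6, year=2019, seed=3)


@pytest.fixture()
def toy_grid():
    """2x2 grid with hand-set layers for arithmetic oracles."""
    import xarray as xr

    def layer(vals):
        return (("row", "col"), np.array(vals, dtype=float))

    data = {
        "MAT": layer([[10.0, 12.0], [14.0, 16.0]]),
        "AAP": layer([[600.0, 700.0], [800.0, 900.0]]),
        "TN": layer([[1.0, 1.1], [1.2, 1.3]]),
        "TP": layer([[0.6, 0.7], [0.8, 0.9]]),
        "AP": layer([[15.0, 18.0], [20.0, 22.0]]),
        "pH": layer([[5.5, 6.0], [6.5, 7.0]]),
        "SOM": layer([[12.0, 15.0], [18.0, 21.0]]),
        "BD": layer([[1.2, 1.3], [1.3, 1.4]]),
        "CheN": layer([[100.0, 150.0], [200.0, 0.0]]),
        "ManN": layer([[50.0, 0.0], [100.0, 0.0]]),
        "cropland_area": layer([[1.0e4, 2.0e4], [3.0e4, 4.0e4]]),
    }
    ds = xr.Dataset(
        data,
        coords={"row": [0, 1], "col": [0, 1]},
        attrs={"year": 2019},
    )
    ds["region_id"] = (("row", "col"), np.array([[0, 0], [1, 1]], dtype=np.int32))
    ds["crop_paddy"] = (("row", "col"), np.array([[0, 1], [0, 1]], dtype=np.int32))
    return ds
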