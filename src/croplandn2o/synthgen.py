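"""Synthetic field observations and gridded covariate time series.

The generator emulates the structure of a national compilation of
chamber-based N2O-N flux experiments: per-region covariate
distributions anchored to regional medians, a nonlinear flux response
surface with an N-source interaction, heteroscedastic measurement
noise, and multi-year gridded driver trends.  Because the true response
surface and driver trends are known, every downstream stage (model
fitting, upscaling, factorial attribution, scenario projection) can be
tested for recovery of a known answer.

Units follow the observation schema: fluxes in kg N2O-N ha-1 (seasonal
or annual cumulative), N inputs in kg N ha-1, MAT in degC, AAP in
mm yr-1, SOM/TN/TP in g kg-1, AP in mg kg-1, BD in g cm-3,
cropland area in ha per cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import schema
from .errors import ConfigError, InputError

#: The five drivers of the factorial attribution protocol, in the order
#: in which they are frozen (climate first, then N management, then
#: cropland distribution).
ATTRIBUTION_DRIVERS = (
    "MAT", "AAP", "total_n_input", "manure_ratio", "cropland",
)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RegionProfile:
    """Median and relative spread of each environmental covariate for
    one agro-region, plus the regional paddy probability."""

    medians: dict[str, float]
    spreads: dict[str, float]
    paddy_fraction: float

    def validate(self) -> None:
        for name in schema.ENV_COVARIATES:
            if name not in self.medians:
                raise ConfigError(f"region profile missing median for {name}")
            if self.spreads.get(name, 0.0) <= 0:
                raise ConfigError(f"non-positive spread for {name}")
        if not 0.0 <= self.paddy_fraction <= 1.0:
            raise ConfigError("paddy_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NInputModel:
    """Distribution of chemical-N and manure-N application rates.

    Treated records are a mixture of chemical-only, manure-only and
    mixed fertilization; the weights must sum to 1.  Rates are sampled
    lognormally so the configured medians are preserved exactly.
    """

    chemical_median: float = 180.0   # kg N/ha
    chemical_sigma: float = 0.60
    manure_median: float = 120.0     # kg N/ha
    manure_sigma: float = 0.60
    w_chemical_only: float = 0.6848
    w_manure_only: float = 0.08
    w_mixed: float = 0.2352

    @property
    def manure_positive_fraction(self) -> float:
        return self.w_manure_only + self.w_mixed

    def validate(self) -> None:
        w = (self.w_chemical_only, self.w_manure_only, self.w_mixed)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError("mixture weights must be >= 0 and sum to 1")
        if min(self.chemical_sigma, self.manure_sigma) <= 0:
            raise ConfigError("rate sigmas must be positive")
        if min(self.chemical_median, self.manure_median) <= 0:
            raise ConfigError("rate medians must be positive")


@dataclass(frozen=True)
class ResponseParams:
    """Coefficients of the true net-flux surface.

    The surface is a saturating response to total N modulated by
    multiplicative environmental factors:

        f = fmax * totalN / (k_n + totalN)
            * g_pH * g_MAT * g_SOM * g_AAP * g_ratio * g_crop

    with an acidity boost below ``ph_mid``, a temperature threshold
    near ``mat_threshold`` (warmer soils emit more), a saturating SOM
    factor (carbon-poor soils emit less), a mild precipitation factor,
    a linear manure-ratio reduction and a paddy suppression factor.
    f(totalN = 0) = 0 by construction.
    """

    fmax: float = 14.0          # kg N2O-N/ha asymptote
    k_n: float = 450.0          # kg N/ha half-saturation
    ph_amp: float = 0.9
    ph_mid: float = 6.0
    ph_width: float = 0.5
    mat_amp: float = 0.35
    mat_threshold: float = 20.0  # degC
    mat_width: float = 2.0
    som_floor: float = 0.45
    som_half: float = 12.0       # g/kg
    aap_amp: float = 0.4
    aap_mid: float = 900.0       # mm/yr
    aap_width: float = 300.0
    ratio_slope: float = 0.35    # manure substitution lowers flux
    paddy_factor: float = 0.60


@dataclass(frozen=True)
class NoiseParams:
    """Heteroscedastic measurement noise on treated fluxes.

    Multiplicative lognormal noise on the (positive) true net flux plus
    a small additive Gaussian term, so slightly negative net fluxes —
    occasionally observed in chamber studies — can occur.  The
    lognormal term is mean-corrected so the noise is unbiased.
    """

    sigma_mult: float = 0.27
    sigma_add: float = 0.30      # kg N2O-N/ha

    def validate(self) -> None:
        if self.sigma_mult < 0 or self.sigma_add < 0:
            raise ConfigError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class GridParams:
    """Controls for gridded covariate fields."""

    autocorr_length: float = 2.0      # cells; 0 = spatially independent
    cropland_fraction: float = 0.8    # probability a cell has cropland
    mean_cell_cropland_ha: float = 5.0e4
    area_sigma: float = 0.7

    def validate(self) -> None:
        if self.autocorr_length < 0:
            raise ConfigError("autocorr_length must be >= 0")
        if not 0.0 <= self.cropland_fraction <= 1.0:
            raise ConfigError("cropland_fraction must lie in [0, 1]")
        if self.mean_cell_cropland_ha < 0 or self.area_sigma <= 0:
            raise ConfigError("invalid cropland area parameters")


def _default_region_profiles() -> dict[str, RegionProfile]:
    # Medians anchored to the regional contrasts of Chinese agro-regions:
    # the Southeast is the most acidic (median pH 5.2) and warmest
    # (median MAT 21.4 degC); the Southwest has the lowest SOM
    # (10.9 g/kg).  Remaining values are realistic regional levels.
    spreads = {"MAT": 2.0, "AAP": 0.25, "TN": 0.30, "TP": 0.30,
               "AP": 0.45, "pH": 0.55, "SOM": 0.35, "BD": 0.08}
    med = {
        "Northeast":       dict(MAT=4.5, AAP=600, TN=1.6, TP=0.8, AP=25, pH=6.5, SOM=30.0, BD=1.25),
        "Northcentral":    dict(MAT=12.5, AAP=550, TN=1.0, TP=0.7, AP=20, pH=7.8, SOM=15.0, BD=1.35),
        "Northwest":       dict(MAT=8.0, AAP=250, TN=0.9, TP=0.7, AP=15, pH=8.2, SOM=12.0, BD=1.40),
        "MidLowerYangtze": dict(MAT=16.5, AAP=1200, TN=1.4, TP=0.6, AP=18, pH=6.2, SOM=22.0, BD=1.30),
        "Southeast":       dict(MAT=21.4, AAP=1700, TN=1.3, TP=0.5, AP=20, pH=5.2, SOM=20.0, BD=1.25),
        "Southwest":       dict(MAT=15.0, AAP=1000, TN=1.2, TP=0.6, AP=15, pH=6.0, SOM=10.9, BD=1.30),
    }
    paddy = {"Northeast": 0.20, "Northcentral": 0.05, "Northwest": 0.02,
             "MidLowerYangtze": 0.60, "Southeast": 0.50, "Southwest": 0.35}
    return {
        name: RegionProfile(medians={k: float(v) for k, v in med[name].items()},
                            spreads=dict(spreads), paddy_fraction=paddy[name])
        for name in schema.REGIONS
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of the synthetic study conditions."""

    region_profiles: dict[str, RegionProfile] = field(default_factory=_default_region_profiles)
    n_input_model: NInputModel = field(default_factory=NInputModel)
    response_params: ResponseParams = field(default_factory=ResponseParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    grid_params: GridParams = field(default_factory=GridParams)
    control_flux_median: float = 0.8     # kg N2O-N/ha background emission
    control_flux_sigma: float = 0.6

    def validate(self) -> None:
        if set(self.region_profiles) != set(schema.REGIONS):
            raise ConfigError("region_profiles must cover exactly the six regions")
        for profile in self.region_profiles.values():
            profile.validate()
        self.n_input_model.validate()
        self.noise_params.validate()
        self.grid_params.validate()
        if self.control_flux_median < 0 or self.control_flux_sigma <= 0:
            raise ConfigError("invalid control flux parameters")


def default_config(**overrides) -> SynthConfig:
    """The default study conditions; keyword overrides replace fields."""
    return replace(SynthConfig(), **overrides) if overrides else SynthConfig()


# ---------------------------------------------------------------------------
# true response surface

def true_net_flux(table: pd.DataFrame, params: ResponseParams) -> np.ndarray:
    """Evaluate the deterministic flux surface on predictor rows."""
    p = params
    total = table["CheN"].to_numpy(float) + table["ManN"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, table["ManN"].to_numpy(float) / np.where(total > 0, total, 1.0), 0.0)
    sat = total / (p.k_n + total)
    g_ph = 1.0 + p.ph_amp / (1.0 + np.exp((table["pH"].to_numpy(float) - p.ph_mid) / p.ph_width))
    g_mat = 1.0 + p.mat_amp / (1.0 + np.exp(-(table["MAT"].to_numpy(float) - p.mat_threshold) / p.mat_width))
    som = table["SOM"].to_numpy(float)
    g_som = p.som_floor + som / (som + p.som_half)
    g_aap = 1.0 - p.aap_amp / 2 + p.aap_amp / (1.0 + np.exp(-(table["AAP"].to_numpy(float) - p.aap_mid) / p.aap_width))
    g_ratio = 1.0 - p.ratio_slope * ratio
    paddy = schema.encode_crop(table["crop"])
    g_crop = np.where(paddy > 0, p.paddy_factor, 1.0)
    return p.fmax * sat * g_ph * g_mat * g_som * g_aap * g_ratio * g_crop


@dataclass
class TruthBundle:
    """Ground truth shipped with every synthetic dataset."""

    response_params: ResponseParams
    true_importance_order: tuple[str, ...]
    driver_trends: dict[str, float] = field(default_factory=dict)

    def true_surface(self, table: pd.DataFrame) -> np.ndarray:
        return true_net_flux(table, self.response_params)

    def to_json(self, path) -> None:
        payload = {
            "response_params": asdict(self.response_params),
            "true_importance_order": list(self.true_importance_order),
            "driver_trends": self.driver_trends,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


#: Ranking of drivers by their variance contribution to the default
#: surface under the default covariate distribution (CheN dominates
#: total N; TN/TP/AP/BD do not enter the surface at all).
TRUE_IMPORTANCE_ORDER = (
    "CheN", "pH", "MAT", "SOM", "ManN", "AAP",
    "manure_ratio", "crop", "TN", "TP", "AP", "BD",
)


# ---------------------------------------------------------------------------
# observation tables

def _sample_env(rng: np.random.Generator, profile: RegionProfile, n: int) -> dict[str, np.ndarray]:
    """Sample environmental covariates for one region.

    Positive, right-skewed covariates are median-preserving lognormals;
    MAT and pH are (truncated) normals around the regional median.
    """
    out: dict[str, np.ndarray] = {}
    for name in schema.ENV_COVARIATES:
        m, s = profile.medians[name], profile.spreads[name]
        if name == "MAT":
            out[name] = rng.normal(m, s, n)
        elif name == "pH":
            vals = rng.normal(m, s, n)
            out[name] = np.clip(vals, 3.0, 10.5)
        else:
            out[name] = m * np.exp(rng.normal(0.0, s, n))
    out["BD"] = np.clip(out["BD"], 0.6, 2.0)
    return out


def _sample_n_inputs(rng: np.random.Generator, model: NInputModel, n: int) -> tuple[np.ndarray, np.ndarray]:
    kinds = rng.choice(3, size=n, p=[model.w_chemical_only, model.w_manure_only, model.w_mixed])
    che = model.chemical_median * np.exp(rng.normal(0.0, model.chemical_sigma, n))
    man = model.manure_median * np.exp(rng.normal(0.0, model.manure_sigma, n))
    che = np.where(kinds == 1, 0.0, che)
    man = np.where(kinds == 0, 0.0, man)
    # mixed records split a comparable total between the two sources
    mixed = kinds == 2
    frac = rng.uniform(0.1, 0.9, n)
    total_mixed = che + man
    che = np.where(mixed, total_mixed * (1 - frac), che)
    man = np.where(mixed, total_mixed * frac, man)
    return che, man


def generate_observation_table(
    config: SynthConfig | None = None,
    n: int = 2186,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Draw ``n`` synthetic field measurements.

    Each record carries the 12 predictors, a non-negative zero-N control
    flux and a treated flux equal to control + true surface + noise.
    Identical (config, n, seed) give identical tables.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(seed)

    regions = rng.choice(len(schema.REGIONS), size=n)
    cols: dict[str, np.ndarray] = {name: np.empty(n) for name in schema.ENV_COVARIATES}
    paddy = np.zeros(n)
    for ridx, rname in enumerate(schema.REGIONS):
        sel = regions == ridx
        m = int(sel.sum())
        if m == 0:
            continue
        profile = config.region_profiles[rname]
        env = _sample_env(rng, profile, m)
        for name in schema.ENV_COVARIATES:
            cols[name][sel] = env[name]
        paddy[sel] = rng.random(m) < profile.paddy_fraction

    che, man = _sample_n_inputs(rng, config.n_input_model, n)

    table = pd.DataFrame(cols)
    table.insert(0, "study_id", [f"S{i:05d}" for i in range(n)])
    table.insert(1, "region", np.array(schema.REGIONS)[regions])
    table["CheN"] = che
    table["ManN"] = man
    table["crop"] = np.where(paddy > 0, "paddy", "upland")

    control = config.control_flux_median * np.exp(
        rng.normal(0.0, config.control_flux_sigma, n))
    surface = true_net_flux(table, config.response_params)
    np_ = config.noise_params
    if np_.sigma_mult > 0:
        mult = np.exp(rng.normal(0.0, np_.sigma_mult, n) - np_.sigma_mult ** 2 / 2)
    else:
        mult = np.ones(n)
    add = rng.normal(0.0, np_.sigma_add, n) if np_.sigma_add > 0 else np.zeros(n)
    table["flux_control"] = control
    table["flux_treated"] = control + surface * mult + add
    table["in_china_field"] = True

    truth = TruthBundle(
        response_params=config.response_params,
        true_importance_order=TRUE_IMPORTANCE_ORDER,
    )
    return table, truth


# ---------------------------------------------------------------------------
# gridded covariates

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """Standardized Gaussian random field with separable-kernel
    autocorrelation of the given length (0 = white noise)."""
    z = rng.standard_normal(shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def _region_map(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Contiguous six-region partition: nearest of six seed points."""
    rows, cols = shape
    seeds_r = rng.uniform(0, rows, len(schema.REGIONS))
    seeds_c = rng.uniform(0, cols, len(schema.REGIONS))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
    return np.argmin(d2, axis=-1).astype(np.int32)


def generate_covariate_grid(
    config: SynthConfig | None = None,
    n_rows: int = 20,
    n_cols: int = 20,
    year: int = 2000,
    seed: int = 0,
) -> xr.Dataset:
    """Generate one year of aligned per-cell covariate layers.

    Covariate fields are spatially smooth around the regional medians;
    cropland area is zero in a configurable fraction of cells; crop
    type follows the regional paddy probability.
    """
    if n_rows < 1 or n_cols < 1:
        raise InputError("grid must have at least one row and one column")
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    gp = config.grid_params

    region_id = _region_map(rng, shape)
    data: dict[str, np.ndarray] = {}
    for name in schema.ENV_COVARIATES:
        z = _smooth_field(rng, shape, gp.autocorr_length)
        medians = np.empty(shape)
        spreads = np.empty(shape)
        for ridx, rname in enumerate(schema.REGIONS):
            profile = config.region_profiles[rname]
            sel = region_id == ridx
            medians[sel] = profile.medians[name]
            spreads[sel] = profile.spreads[name]
        if name == "MAT":
            data[name] = medians + spreads * z
        elif name == "pH":
            data[name] = np.clip(medians + spreads * z, 3.0, 10.5)
        elif name == "BD":
            data[name] = np.clip(medians * np.exp(spreads * z), 0.6, 2.0)
        else:
            data[name] = medians * np.exp(spreads * z)

    nim = config.n_input_model
    data["CheN"] = nim.chemical_median * np.exp(
        nim.chemical_sigma * _smooth_field(rng, shape, gp.autocorr_length))
    manure_share = 0.15 * np.exp(
        0.5 * _smooth_field(rng, shape, gp.autocorr_length))
    data["ManN"] = data["CheN"] * np.clip(manure_share, 0.0, 1.0)

    has_cropland = rng.random(shape) < gp.cropland_fraction
    area = gp.mean_cell_cropland_ha * np.exp(
        rng.normal(0.0, gp.area_sigma, shape))
    data["cropland_area"] = np.where(has_cropland, area, 0.0)

    paddy_p = np.empty(shape)
    for ridx, rname in enumerate(schema.REGIONS):
        paddy_p[region_id == ridx] = config.region_profiles[rname].paddy_fraction
    data["crop_paddy"] = (rng.random(shape) < paddy_p).astype(np.int32)
    data["region_id"] = region_id

    grid = xr.Dataset(
        {name: (("row", "col"), arr) for name, arr in data.items()},
        coords={"row": np.arange(n_rows), "col": np.arange(n_cols)},
        attrs={"year": int(year), "regions": list(schema.REGIONS),
               "resolution": "synthetic-cell", "origin": "0,0"},
    )
    schema.validate_grid(grid)
    return grid


# ---------------------------------------------------------------------------
# multi-year driver trends

@dataclass(frozen=True)
class Trend:
    """Linear-in-time trend for one driver.

    ``final_factor`` is the multiplier reached in the last year
    (mode "multiply") or the additive offset reached in the last year
    (mode "add"); intermediate years interpolate linearly, and the
    first year is always unchanged.
    """

    final_factor: float = 1.0
    mode: str = "multiply"

    def at(self, frac: float) -> float:
        if self.mode == "multiply":
            return 1.0 + frac * (self.final_factor - 1.0)
        if self.mode == "add":
            return frac * self.final_factor
        raise ConfigError(f"unknown trend mode {self.mode!r}")

    @property
    def is_identity(self) -> bool:
        return (self.mode == "multiply" and self.final_factor == 1.0) or (
            self.mode == "add" and self.final_factor == 0.0)


@dataclass
class GridSeries:
    """Covariate grids for an ordered list of years."""

    years: list[int]
    grids: dict[int, xr.Dataset]

    def __iter__(self):
        return (self.grids[y] for y in self.years)

    def __len__(self):
        return len(self.years)

    def __getitem__(self, year: int) -> xr.Dataset:
        return self.grids[year]


def identity_trends() -> dict[str, Trend]:
    return {d: Trend() for d in ATTRIBUTION_DRIVERS}


def generate_grid_series(
    config: SynthConfig | None = None,
    years: list[int] | None = None,
    trend_spec: Mapping[str, Trend] | None = None,
    seed: int = 0,
    n_rows: int = 20,
    n_cols: int = 20,
) -> GridSeries:
    """Generate a multi-year grid series with per-driver trends.

    The first year's grid is drawn once; later years apply the trend of
    each of the five attribution drivers to that base grid while every
    other layer is held bitwise constant.  Drivers with an identity
    trend are therefore constant across years, and the first-year grid
    does not depend on the trend specification.
    """
    years = list(years or [2000, 2019])
    if len(years) < 2:
        raise InputError("a grid series needs at least two years")
    trends = dict(identity_trends())
    if trend_spec:
        unknown = set(trend_spec) - set(ATTRIBUTION_DRIVERS)
        if unknown:
            raise ConfigError(f"unknown attribution drivers: {sorted(unknown)}")
        trends.update(trend_spec)

    base = generate_covariate_grid(config, n_rows, n_cols, year=years[0], seed=seed)
    total0 = base["CheN"].values + base["ManN"].values
    with np.errstate(invalid="ignore"):
        ratio0 = np.where(total0 > 0, base["ManN"].values / np.where(total0 > 0, total0, 1.0), 0.0)

    grids: dict[int, xr.Dataset] = {years[0]: base}
    span = years[-1] - years[0]
    for y in years[1:]:
        frac = (y - years[0]) / span
        g = base.copy(deep=True)
        g.attrs = dict(base.attrs, year=int(y))
        if not trends["MAT"].is_identity:
            f = trends["MAT"].at(frac)
            g["MAT"] = g["MAT"] * f if trends["MAT"].mode == "multiply" else g["MAT"] + f
        if not trends["AAP"].is_identity:
            f = trends["AAP"].at(frac)
            g["AAP"] = g["AAP"] * f if trends["AAP"].mode == "multiply" else g["AAP"] + f
        total = total0.copy()
        ratio = ratio0.copy()
        if not trends["total_n_input"].is_identity:
            total = total0 * trends["total_n_input"].at(frac)
        if not trends["manure_ratio"].is_identity:
            ratio = np.clip(ratio0 * trends["manure_ratio"].at(frac), 0.0, 1.0)
        if not (trends["total_n_input"].is_identity and trends["manure_ratio"].is_identity):
            g["CheN"] = (("row", "col"), total * (1.0 - ratio))
            g["ManN"] = (("row", "col"), total * ratio)
        if not trends["cropland"].is_identity:
            g["cropland_area"] = g["cropland_area"] * trends["cropland"].at(frac)
        grids[y] = g
    return GridSeries(years=years, grids=grids)
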