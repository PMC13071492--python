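"""Canonical column names, grid layers and region labels.

Every stage exchanges data either as a pandas DataFrame of field
observations or as an xarray Dataset of aligned per-cell covariate
layers.  This module is the single source of truth for the names and
units of both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .errors import AlignmentError, SchemaError

#: The 12 predictors of net cumulative N2O-N flux, in canonical order:
#: climate (MAT degC, AAP mm/yr), soil (TN g/kg, TP g/kg, AP mg/kg, pH,
#: SOM g/kg, BD g/cm3), N management (CheN and ManN in kg N/ha,
#: manure_ratio = ManN / (CheN + ManN)), and cropping system
#: (crop: "paddy" or "upland").
PREDICTORS = (
    "MAT", "AAP", "TN", "TP", "AP", "pH", "SOM", "BD",
    "CheN", "ManN", "manure_ratio", "crop",
)

#: Environmental covariates sampled directly from regional profiles.
ENV_COVARIATES = ("MAT", "AAP", "TN", "TP", "AP", "pH", "SOM", "BD")

#: Flux columns of an observation table (kg N2O-N / ha, cumulative).
FLUX_COLUMNS = ("flux_control", "flux_treated")

#: Six agro-climatic regions used for regional aggregation.
REGIONS = (
    "Northeast", "Northcentral", "Northwest",
    "MidLowerYangtze", "Southeast", "Southwest",
)

#: Grid layers required to evaluate the flux model on a covariate grid.
#: ``crop_paddy`` is the binary encoding of the crop layer (paddy=1),
#: ``region_id`` indexes into REGIONS, ``cropland_area`` is ha per cell.
GRID_LAYERS = ENV_COVARIATES + (
    "CheN", "ManN", "cropland_area", "region_id", "crop_paddy",
)

CROP_LEVELS = ("upland", "paddy")


def encode_crop(crop: pd.Series | np.ndarray) -> np.ndarray:
    """Encode the crop column as a binary indicator (paddy=1)."""
    arr = np.asarray(crop)
    if arr.dtype.kind in "ifb":
        return arr.astype(float)
    return (arr == "paddy").astype(float)


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Return the numeric 12-column model matrix in canonical order."""
    missing = [c for c in PREDICTORS if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing predictor columns: {missing}")
    X = table[list(PREDICTORS)].copy()
    X["crop"] = encode_crop(X["crop"])
    return X.astype(float)


def manure_ratio_layer(grid: xr.Dataset) -> xr.DataArray:
    """Per-cell ManN/(CheN+ManN); defined as 0 where total N is 0."""
    total = grid["CheN"] + grid["ManN"]
    ratio = xr.where(total > 0, grid["ManN"] / xr.where(total > 0, total, 1.0), 0.0)
    return ratio.rename("manure_ratio")


def validate_grid(grid: xr.Dataset) -> None:
    """Check that a covariate grid carries every required layer with
    consistent values; raise SchemaError otherwise."""
    missing = [v for v in GRID_LAYERS if v not in grid.data_vars]
    if missing:
        raise SchemaError(f"grid is missing layers: {missing}")
    if bool((grid["cropland_area"] < 0).any()):
        raise SchemaError("cropland_area contains negative values")
    if bool((grid["CheN"] < 0).any()) or bool((grid["ManN"] < 0).any()):
        raise SchemaError("N input layers contain negative values")
    rid = grid["region_id"].values
    if rid.min() < 0 or rid.max() >= len(REGIONS):
        raise SchemaError("region_id outside the six-region label set")


def check_aligned(a: xr.Dataset, b: xr.Dataset) -> None:
    """Raise AlignmentError unless the two grids share shape and dims."""
    sa = {d: a.sizes[d] for d in ("row", "col")}
    sb = {d: b.sizes[d] for d in ("row", "col")}
    if sa != sb:
        raise AlignmentError(f"grid shapes differ: {sa} vs {sb}")


def grid_to_frame(grid: xr.Dataset, mask: xr.DataArray | None = None) -> pd.DataFrame:
    """Flatten (masked) grid cells into an observation-style predictor
    frame whose row order follows row-major cell order."""
    validate_grid(grid)
    ratio = manure_ratio_layer(grid)
    flat = {}
    for name in ENV_COVARIATES + ("CheN", "ManN"):
        flat[name] = grid[name].values.ravel()
    flat["manure_ratio"] = ratio.values.ravel()
    crop = np.where(grid["crop_paddy"].values.ravel() > 0, "paddy", "upland")
    flat["crop"] = crop
    frame = pd.DataFrame(flat)
    if mask is not None:
        frame = frame[mask.values.ravel()].reset_index(drop=True)
    return frame


def save_grid(grid: xr.Dataset, path) -> None:
    """Write a covariate grid as NetCDF-3 (scipy backend)."""
    enc = grid.copy()
    for name in ("region_id", "crop_paddy"):
        enc[name] = enc[name].astype(np.int32)
    # NetCDF-3 attributes cannot hold string arrays
    enc.attrs = {k: (",".join(v) if isinstance(v, (list, tuple)) else v)
                 for k, v in grid.attrs.items()}
    enc.to_netcdf(path, engine="scipy")


def load_grid(path) -> xr.Dataset:
    grid = xr.load_dataset(path, engine="scipy")
    if isinstance(grid.attrs.get("regions"), str):
        grid.attrs["regions"] = grid.attrs["regions"].split(",")
    validate_grid(grid)
    return grid
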