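"""Gridded prediction and regional/national aggregation.

A fitted flux model is applied per cell to a covariate grid; cells are
evaluated exactly where cropland area and total N input are positive.
Cell losses (kg = flux kg/ha x cropland ha) are summed to regional and
national totals in Gg (1 Gg = 1e6 kg), with the national total defined
as the exact sum of the regional totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import xarray as xr

from . import schema
from .errors import AlignmentError, InputError, SchemaError

KG_PER_GG = 1.0e6


@dataclass
class FluxGrid:
    """Per-cell predicted net flux with its evaluation mask."""

    flux: xr.DataArray          # kg N2O-N/ha; NaN outside the mask
    mask: xr.DataArray          # True where evaluated
    year: int | None = None


@dataclass
class AggregateReport:
    """National and regional N2O-N losses for one grid."""

    national_total_gg: float
    region_totals_gg: dict[str, float]
    region_share_pct: dict[str, float]
    flux_median: float          # unweighted over evaluated cells, kg/ha
    flux_sd: float
    flux_median_area_weighted: float
    n_cells: int
    year: int | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def predict_flux_grid(model, grid: xr.Dataset) -> FluxGrid:
    """Evaluate the model on every cropland cell with positive N input.

    Cellwise predictions are identical to applying the model to the
    equivalent row table; non-cropland and zero-N cells are masked and
    never passed to the model.
    """
    schema.validate_grid(grid)
    total = grid["CheN"] + grid["ManN"]
    mask = (grid["cropland_area"] > 0) & (total > 0)
    frame = schema.grid_to_frame(grid, mask=mask)
    flux = xr.full_like(grid["CheN"].astype(float), np.nan).rename("net_flux")
    if len(frame):
        values = model.predict(frame)
        buf = flux.values.ravel()
        buf[mask.values.ravel()] = values
        flux = xr.DataArray(buf.reshape(flux.shape), dims=("row", "col"),
                            coords=flux.coords, name="net_flux")
    return FluxGrid(flux=flux, mask=mask, year=grid.attrs.get("year"))


def aggregate_loss(flux: FluxGrid, grid: xr.Dataset,
                   clip_negative: bool = False) -> AggregateReport:
    """Aggregate per-cell losses to regional and national totals.

    Negative predicted fluxes are retained by default (the model's
    target is a net flux); ``clip_negative=True`` floors cell fluxes at
    zero for sensitivity runs.  Masked cells contribute nothing to the
    totals and are excluded from the median/SD summaries.
    """
    if flux.flux.shape != grid["cropland_area"].shape:
        raise AlignmentError(
            f"flux shape {flux.flux.shape} does not match grid shape "
            f"{grid['cropland_area'].shape}")
    m = flux.mask.values.ravel()
    fvals = flux.flux.values.ravel()[m]
    if clip_negative:
        fvals = np.clip(fvals, 0.0, None)
    area = grid["cropland_area"].values.ravel()[m]
    region = grid["region_id"].values.ravel()[m]
    loss_gg = fvals * area / KG_PER_GG

    region_totals: dict[str, float] = {}
    for ridx, rname in enumerate(schema.REGIONS):
        region_totals[rname] = float(loss_gg[region == ridx].sum())
    national = float(sum(region_totals.values()))
    if national != 0.0:
        shares = {r: 100.0 * t / national for r, t in region_totals.items()}
    else:
        shares = {r: float("nan") for r in region_totals}

    if fvals.size:
        order = np.argsort(fvals, kind="stable")
        cum = np.cumsum(area[order])
        aw_median = float(fvals[order][np.searchsorted(cum, cum[-1] / 2.0)]) if cum[-1] > 0 else float("nan")
        med, sd = float(np.median(fvals)), float(np.std(fvals))
    else:
        med = sd = aw_median = float("nan")
    return AggregateReport(
        national_total_gg=national, region_totals_gg=region_totals,
        region_share_pct=shares, flux_median=med, flux_sd=sd,
        flux_median_area_weighted=aw_median, n_cells=int(fvals.size),
        year=flux.year)


def series_losses(model, series) -> list[AggregateReport]:
    """One aggregate report per year of a grid series."""
    if len(series) == 0:
        raise InputError("grid series is empty")
    shapes = {tuple(g.sizes[d] for d in ("row", "col")) for g in series}
    if len(shapes) > 1:
        raise SchemaError(f"grids in the series have inconsistent shapes: {shapes}")
    reports = []
    for grid in series:
        fg = predict_flux_grid(model, grid)
        reports.append(aggregate_loss(fg, grid))
    return reports
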