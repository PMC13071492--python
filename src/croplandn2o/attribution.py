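"""Factorial counterfactual attribution of N2O-N loss trends.

Starting from the end-year grid (S0), drivers are frozen one at a time
at their start-year state, in a fixed order: MAT (S1), AAP (S2), total
N input while keeping the end-year manure ratio (S3), manure ratio
(S4), and cropland distribution (S5, which reproduces the start-year
grid exactly).  The difference between successive simulation totals
assigns the change in national loss to each driver; by construction
the five deltas telescope to total(S0) - total(S5) exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import xarray as xr

from . import schema, upscale
from .errors import AlignmentError, InputError
from .synthgen import ATTRIBUTION_DRIVERS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorialPlan:
    """Freezing order and period of the factorial protocol."""

    t1: int
    t2: int
    drivers: tuple[str, ...] = ATTRIBUTION_DRIVERS

    def validate(self) -> None:
        if self.drivers != ATTRIBUTION_DRIVERS:
            raise InputError("driver freezing order is fixed: "
                             f"{ATTRIBUTION_DRIVERS}")
        if not self.t1 < self.t2:
            raise InputError("t1 must precede t2")


@dataclass
class AttributionResult:
    """Per-driver change in national loss and simulation totals."""

    totals_gg: list[float]                 # totals for S0..S5
    deltas_gg: dict[str, float]            # per-driver Gg
    percents: dict[str, float] | None      # signed % of |total change|
    plan: FactorialPlan | None = None
    ratio_fallback_cells: int = 0

    @property
    def total_change_gg(self) -> float:
        return self.totals_gg[0] - self.totals_gg[-1]

    def to_json(self, path=None) -> str:
        payload = {
            "totals_gg": self.totals_gg,
            "deltas_gg": self.deltas_gg,
            "percents": self.percents,
            "total_change_gg": self.total_change_gg,
            "percent_normalization":
                "100 * delta / |total(S0) - total(S5)|, sign preserved",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _ratio(grid: xr.Dataset) -> tuple[np.ndarray, np.ndarray]:
    total = grid["CheN"].values + grid["ManN"].values
    ratio = np.where(total > 0, grid["ManN"].values / np.where(total > 0, total, 1.0), 0.0)
    return total, ratio


def build_factorial_inputs(grid_t1: xr.Dataset, grid_t2: xr.Dataset,
                           plan: FactorialPlan | None = None
                           ) -> tuple[list[xr.Dataset], int]:
    """Construct the six counterfactual grids S0..S5.

    S3 fixes per-cell total N at its T1 value while the manure ratio
    keeps its T2 value (CheN' = totalN_T1 * (1 - ratio_T2),
    ManN' = totalN_T1 * ratio_T2).  Cells with positive T1 total but no
    T2 input have an undefined T2 ratio; these fall back to the T1
    ratio and are counted.  S5 is the T1 grid itself.
    """
    if plan is not None:
        plan.validate()
    schema.validate_grid(grid_t1)
    schema.validate_grid(grid_t2)
    schema.check_aligned(grid_t1, grid_t2)

    total1, ratio1 = _ratio(grid_t1)
    total2, ratio2 = _ratio(grid_t2)
    undefined = (total1 > 0) & (total2 == 0)
    n_fallback = int(undefined.sum())
    if n_fallback:
        logger.info("%d cells lack a T2 manure ratio; falling back to T1 ratio",
                    n_fallback)
    ratio_for_s3 = np.where(undefined, ratio1, ratio2)

    s0 = grid_t2.copy(deep=True)
    s1 = s0.copy(deep=True)
    s1["MAT"] = grid_t1["MAT"].copy()
    s2 = s1.copy(deep=True)
    s2["AAP"] = grid_t1["AAP"].copy()
    s3 = s2.copy(deep=True)
    # keep the T2 layers bitwise where the cell total did not change
    same = total1 == total2
    s3["CheN"] = (("row", "col"), np.where(same, grid_t2["CheN"].values,
                                           total1 * (1.0 - ratio_for_s3)))
    s3["ManN"] = (("row", "col"), np.where(same, grid_t2["ManN"].values,
                                           total1 * ratio_for_s3))
    s4 = s3.copy(deep=True)
    s4["CheN"] = grid_t1["CheN"].copy()
    s4["ManN"] = grid_t1["ManN"].copy()
    s5 = grid_t1.copy(deep=True)
    return [s0, s1, s2, s3, s4, s5], n_fallback


def run_attribution(model, grids: list[xr.Dataset],
                    plan: FactorialPlan | None = None,
                    ratio_fallback_cells: int = 0) -> AttributionResult:
    """Evaluate the model on S0..S5 and attribute the total change.

    delta_k = total(S_{k-1}) - total(S_k) is assigned to the k-th
    driver; percents normalize each delta by the absolute total change
    with sign preserved (undefined if the total change is zero).
    """
    if len(grids) != len(ATTRIBUTION_DRIVERS) + 1:
        raise InputError("expected the six factorial grids S0..S5")
    totals = []
    for g in grids:
        fg = upscale.predict_flux_grid(model, g)
        totals.append(upscale.aggregate_loss(fg, g).national_total_gg)
    deltas = {drv: totals[k] - totals[k + 1]
              for k, drv in enumerate(ATTRIBUTION_DRIVERS)}
    change = totals[0] - totals[-1]
    if change != 0.0:
        percents = {d: 100.0 * v / abs(change) for d, v in deltas.items()}
    else:
        percents = None
        logger.warning("total change is zero; percents undefined")
    return AttributionResult(totals_gg=totals, deltas_gg=deltas,
                             percents=percents, plan=plan,
                             ratio_fallback_cells=ratio_fallback_cells)


@dataclass
class TelescopingReport:
    passed: bool
    residual_gg: float
    tol_gg: float


def verify_telescoping(result: AttributionResult, tol: float = 1e-9
                       ) -> TelescopingReport:
    """Check that the driver deltas sum to total(S0) - total(S5)."""
    residual = abs(sum(result.deltas_gg.values()) - result.total_change_gg)
    return TelescopingReport(passed=residual <= tol, residual_gg=residual,
                             tol_gg=tol)


def attribute_change(model, grid_t1: xr.Dataset, grid_t2: xr.Dataset,
                     plan: FactorialPlan | None = None) -> AttributionResult:
    """Convenience wrapper: build the factorial grids and attribute."""
    grids, n_fb = build_factorial_inputs(grid_t1, grid_t2, plan)
    return run_attribution(model, grids, plan, ratio_fallback_cells=n_fb)
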