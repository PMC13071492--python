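"""Manure-substitution scenario engine.

Each scenario is a national nitrogen budget: manure-N in livestock
excreta (Tg) times the manure recycling rate gives the total manure-N
returned to cropland; multiplying by the manure-N fertilizer
equivalency (MFE, the plant-available fraction after storage,
processing and spreading losses) gives the available manure-N.  With a
fixed national plant-available-N target, the available chemical-N is
the remainder, and the substitution ratio is the available manure
share of the target.  Scenario budgets translate into two spatially
uniform scaling factors applied to the baseline-year gridded manure-N
and chemical-N application rates.

All internal arithmetic is unrounded; printed-table style reporting
rounds half-up to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
import xarray as xr

from . import schema, upscale
from .errors import AlignmentError, ConfigError, InfeasibleScenarioError, InputError


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed budget
    tables; Python's round() is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScenarioParams:
    """National budget inputs for one scenario or historical year.

    Exactly one of ``total_available_n_target_tg`` (2050 scenarios,
    where the plant-available supply is fixed) or
    ``available_chemical_n_tg`` (historical years, where chemical use
    is observed) must be given; the other is derived.
    """

    name: str
    excreta_manure_n_tg: float
    recycling_rate: float            # fraction of excreted N recycled
    mfe: float                       # plant-available fraction
    total_available_n_target_tg: float | None = None
    available_chemical_n_tg: float | None = None

    def validate(self) -> None:
        if not 0.0 <= self.recycling_rate <= 1.0:
            raise ConfigError("recycling_rate must lie in [0, 1]")
        if not 0.0 < self.mfe <= 1.0:
            raise ConfigError("mfe must lie in (0, 1]")
        if self.excreta_manure_n_tg < 0:
            raise ConfigError("excreta manure-N must be >= 0")
        given = [self.total_available_n_target_tg, self.available_chemical_n_tg]
        if sum(v is not None for v in given) != 1:
            raise ConfigError("give exactly one of the available-N target "
                              "or the available chemical-N input")


@dataclass(frozen=True)
class ScenarioBudget:
    """Derived national N accounts (unrounded)."""

    name: str
    total_manure_n_input_tg: float
    available_manure_n_tg: float
    available_chemical_n_tg: float
    total_available_n_tg: float
    substitution_ratio_pct: float

    def rounded(self) -> dict[str, float]:
        return {k: round_half_up(v) for k, v in asdict(self).items()
                if isinstance(v, float)}


#: The eight columns of the historical/scenario parameter table.
#: Historical years fix the observed chemical-N input; 2050 scenarios
#: fix the plant-available-N target at the BAU level (28.59 Tg).
PRESETS: dict[str, ScenarioParams] = {
    "2000": ScenarioParams("2000", 13.56, 0.3373, 0.30, available_chemical_n_tg=22.14),
    "2014": ScenarioParams("2014", 12.75, 0.3733, 0.30, available_chemical_n_tg=30.98),
    "2019": ScenarioParams("2019", 12.43, 0.3517, 0.30, available_chemical_n_tg=23.02),
    "BAU": ScenarioParams("BAU", 23.97, 0.3517, 0.30, total_available_n_target_tg=28.59),
    "HMR": ScenarioParams("HMR", 23.97, 0.50, 0.30, total_available_n_target_tg=28.59),
    "FMR": ScenarioParams("FMR", 23.97, 1.00, 0.30, total_available_n_target_tg=28.59),
    "HMR_MFE50": ScenarioParams("HMR_MFE50", 23.97, 0.50, 0.50, total_available_n_target_tg=28.59),
    "FMR_MFE50": ScenarioParams("FMR_MFE50", 23.97, 1.00, 0.50, total_available_n_target_tg=28.59),
}

BASELINE_YEAR = "2019"


def compute_budget(params: ScenarioParams) -> ScenarioBudget:
    """Derive the full N budget from the four primitive quantities.

    available_manure = excreta x recycling x MFE (unrounded);
    available_chemical = target - available_manure, which must be
    non-negative or the scenario is infeasible.
    """
    params.validate()
    total_manure = params.excreta_manure_n_tg * params.recycling_rate
    available_manure = total_manure * params.mfe
    if params.total_available_n_target_tg is not None:
        target = params.total_available_n_target_tg
        chemical = target - available_manure
        if chemical < 0:
            raise InfeasibleScenarioError(
                f"{params.name}: available manure-N {available_manure:.3f} Tg "
                f"exceeds the available-N target {target:.3f} Tg")
    else:
        chemical = params.available_chemical_n_tg
        target = chemical + available_manure
    substitution = 100.0 * available_manure / target if target > 0 else float("nan")
    return ScenarioBudget(
        name=params.name,
        total_manure_n_input_tg=total_manure,
        available_manure_n_tg=available_manure,
        available_chemical_n_tg=chemical,
        total_available_n_tg=target,
        substitution_ratio_pct=substitution,
    )


@dataclass(frozen=True)
class ScalingFactors:
    """Spatially uniform multipliers for the baseline gridded N maps."""

    manure_scale: float
    chemical_scale: float


def derive_scaling_factors(budget: ScenarioBudget,
                           baseline: ScenarioBudget) -> ScalingFactors:
    """Scenario-to-baseline ratios of national N inputs.

    Ratios are taken between the report-rounded (half-up, 2-decimal)
    totals, matching the arithmetic of the published parameter tables
    (e.g. full recycling: 23.97 / 4.37 = 5.49).
    """
    base_man = round_half_up(baseline.total_manure_n_input_tg)
    base_chem = round_half_up(baseline.available_chemical_n_tg)
    if base_man <= 0 or base_chem <= 0:
        raise InputError("baseline totals must be positive")
    return ScalingFactors(
        manure_scale=round_half_up(budget.total_manure_n_input_tg) / base_man,
        chemical_scale=round_half_up(budget.available_chemical_n_tg) / base_chem,
    )


def budget_table(names: list[str] | None = None) -> pd.DataFrame:
    """Reconstruct the full scenario parameter table (rounded view),
    with scaling factors relative to the baseline year where defined."""
    names = names or list(PRESETS)
    baseline = compute_budget(PRESETS[BASELINE_YEAR])
    rows = {}
    for name in names:
        params = PRESETS[name]
        budget = compute_budget(params)
        row = {
            "excreta_manure_n_tg": params.excreta_manure_n_tg,
            "recycling_rate_pct": round_half_up(100 * params.recycling_rate),
            "total_manure_n_input_tg": round_half_up(budget.total_manure_n_input_tg),
            "mfe_pct": round_half_up(100 * params.mfe),
            "available_manure_n_tg": round_half_up(budget.available_manure_n_tg),
            "available_chemical_n_tg": round_half_up(budget.available_chemical_n_tg),
            "total_available_n_tg": round_half_up(budget.total_available_n_tg),
            "substitution_ratio_pct": round_half_up(budget.substitution_ratio_pct),
        }
        if params.total_available_n_target_tg is not None:
            scales = derive_scaling_factors(budget, baseline)
            row["manure_scale"] = round_half_up(scales.manure_scale)
            row["chemical_scale"] = round_half_up(scales.chemical_scale)
        rows[name] = row
    return pd.DataFrame(rows).T


def apply_scenario(base_grid: xr.Dataset, scales: ScalingFactors,
                   climate: xr.Dataset | None = None,
                   cropland: xr.Dataset | None = None) -> xr.Dataset:
    """Build a scenario covariate grid from the baseline-year grid.

    ManN and CheN layers are scaled uniformly; MAT/AAP are replaced by
    the scenario climate layers and cropland area/type by the scenario
    cropland layers when provided; soil layers are unchanged.  The
    manure ratio is implied per cell by the scaled N layers.
    """
    schema.validate_grid(base_grid)
    out = base_grid.copy(deep=True)
    out["ManN"] = base_grid["ManN"] * scales.manure_scale
    out["CheN"] = base_grid["CheN"] * scales.chemical_scale
    if climate is not None:
        schema.check_aligned(base_grid, climate)
        for name in ("MAT", "AAP"):
            if name in climate:
                out[name] = climate[name].copy()
    if cropland is not None:
        schema.check_aligned(base_grid, cropland)
        for name in ("cropland_area", "crop_paddy"):
            if name in cropland:
                out[name] = cropland[name].copy()
    return out


@dataclass
class ScenarioReport:
    """Projected national loss and relative changes."""

    name: str
    national_loss_gg: float
    delta_vs_baseline_pct: float | None
    delta_vs_bau_pct: float | None
    region_totals_gg: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def percent_change(value: float, reference: float) -> float:
    """Signed relative change, in percent of the reference."""
    if reference == 0:
        raise InputError("relative change undefined for a zero reference")
    return 100.0 * (value - reference) / reference


def project_and_compare(model, scenario_grid: xr.Dataset, name: str,
                        baseline_report: upscale.AggregateReport,
                        bau_report: upscale.AggregateReport | None = None
                        ) -> ScenarioReport:
    """Upscale the scenario grid and compare with baseline and BAU."""
    fg = upscale.predict_flux_grid(model, scenario_grid)
    agg = upscale.aggregate_loss(fg, scenario_grid)
    d_base = (percent_change(agg.national_total_gg, baseline_report.national_total_gg)
              if baseline_report.national_total_gg != 0 else None)
    d_bau = None
    if bau_report is not None and bau_report.national_total_gg != 0:
        d_bau = percent_change(agg.national_total_gg, bau_report.national_total_gg)
    return ScenarioReport(name=name, national_loss_gg=agg.national_total_gg,
                          delta_vs_baseline_pct=d_base, delta_vs_bau_pct=d_bau,
                          region_totals_gg=agg.region_totals_gg)
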