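"""Curation of field observation tables.

Screening follows the compilation's inclusion criteria: the experiment
must be a fertilization study (positive N input in the treated plot),
conducted under field conditions in China, and report cumulative
N2O-N fluxes for both a zero-N reference treatment and the N-input
treatment.  Net flux and fertilizer-induced emission factors are
computed from the paired fluxes; derived features (total N, manure
ratio) feed the regression models.
"""

from __future__ import annotations

import logging
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ConfigError, SchemaError

logger = logging.getLogger(__name__)

#: Screening criteria in the order they are applied; each excluded
#: record is counted under the first criterion it fails.
SCREENING_CRITERIA = (
    "missing_covariate",
    "not_fertilization",
    "not_field",
    "missing_control",
    "missing_treated",
)

REQUIRED_RAW_COLUMNS = (
    "MAT", "AAP", "TN", "TP", "AP", "pH", "SOM", "BD",
    "CheN", "ManN", "crop", "flux_control", "flux_treated",
)


@dataclass
class ScreeningReport:
    """Per-criterion exclusion counts; excluded + retained = input size."""

    excluded: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    total: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())

    def check_conservation(self) -> bool:
        return self.n_excluded + self.retained == self.total

    def to_json(self, path=None) -> str:
        payload = {"total": self.total, "retained": self.retained,
                   "excluded": self.excluded}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def screen_records(raw: pd.DataFrame, criteria: tuple[str, ...] = SCREENING_CRITERIA
                   ) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply the inclusion criteria; return the retained table and a
    report accounting for every input record exactly once."""
    if raw is None or len(raw) == 0:
        raise InputError("screening requires a non-empty observation table")
    missing_cols = [c for c in REQUIRED_RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"observation table missing columns: {missing_cols}")

    n = len(raw)
    failed = pd.Series("", index=raw.index, dtype=object)

    def _flag(mask: pd.Series, name: str) -> None:
        mask = mask & (failed == "")
        failed[mask] = name

    covars = raw[["MAT", "AAP", "TN", "TP", "AP", "pH", "SOM", "BD", "CheN", "ManN"]]
    if "missing_covariate" in criteria:
        _flag(covars.isna().any(axis=1) | raw["crop"].isna(), "missing_covariate")
    if "not_fertilization" in criteria:
        total = raw["CheN"].fillna(0) + raw["ManN"].fillna(0)
        _flag(~(total > 0), "not_fertilization")
    if "not_field" in criteria and "in_china_field" in raw.columns:
        _flag(~raw["in_china_field"].fillna(False).astype(bool), "not_field")
    if "missing_control" in criteria:
        _flag(~np.isfinite(raw["flux_control"].astype(float)), "missing_control")
    if "missing_treated" in criteria:
        _flag(~np.isfinite(raw["flux_treated"].astype(float)), "missing_treated")

    keep = failed == ""
    counts = failed[~keep].value_counts().to_dict()
    report = ScreeningReport(excluded={k: int(v) for k, v in counts.items()},
                             retained=int(keep.sum()), total=n)
    assert report.check_conservation()
    retained = raw[keep].reset_index(drop=True)
    if report.n_excluded:
        logger.info("screening excluded %d of %d records: %s",
                    report.n_excluded, n, report.excluded)
    return retained, report


def compute_net_flux(record: pd.Series | pd.DataFrame):
    """Net cumulative flux = treated - control (kg N2O-N/ha).

    May be negative (net uptake under fertilization); negative values
    are retained and logged, never clipped.
    """
    treated, control = record["flux_treated"], record["flux_control"]
    if isinstance(record, pd.DataFrame):
        if treated.isna().any() or control.isna().any():
            raise InputError("net flux requires both treated and control fluxes")
        net = treated - control
        n_neg = int((net < 0).sum())
        if n_neg:
            logger.info("%d records show negative net flux (net uptake)", n_neg)
        return net
    if treated is None or control is None or math.isnan(float(treated)) or math.isnan(float(control)):
        raise InputError("net flux requires both treated and control fluxes")
    net = float(treated) - float(control)
    if net < 0:
        logger.info("negative net flux %.3f kg/ha (net uptake)", net)
    return net


def compute_emission_factor(record: pd.Series | pd.DataFrame):
    """Fertilizer-induced emission factor in percent:
    EF% = 100 * (treated - control) / (CheN + ManN)."""
    total = record["CheN"] + record["ManN"]
    bad = (total <= 0) if not np.isscalar(total) else total <= 0
    if (bad.any() if hasattr(bad, "any") else bad):
        raise InputError("emission factor undefined for total N input <= 0")
    return 100.0 * compute_net_flux(record) / total


def derive_features(table: pd.DataFrame) -> pd.DataFrame:
    """Populate totalN, manure_ratio and net_flux columns.

    manure_ratio is 0 for chemical-only records and 1 for manure-only
    records; rows with zero total N violate the inclusion criteria and
    are rejected.
    """
    out = table.copy()
    total = out["CheN"].astype(float) + out["ManN"].astype(float)
    if (total <= 0).any():
        raise InputError("rows with zero total N input must be screened out first")
    out["totalN"] = total
    out["manure_ratio"] = out["ManN"].astype(float) / total
    out["net_flux"] = compute_net_flux(out)
    return out


def split_dev_test(table: pd.DataFrame, dev_fraction: float = 0.9, seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-deterministic disjoint, exhaustive dev/test partition.

    The development set receives floor(n * dev_fraction) rows and the
    remainder goes to the test set (2186 rows at 0.9 -> 1967 / 219).
    """
    n = len(table)
    if n < 10:
        raise InputError("need at least 10 rows to split")
    if not 0.0 < dev_fraction < 1.0:
        raise ConfigError("dev_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_dev = int(math.floor(n * dev_fraction))
    dev_idx, test_idx = np.sort(perm[:n_dev]), np.sort(perm[n_dev:])
    dev = table.iloc[dev_idx].reset_index(drop=True)
    test = table.iloc[test_idx].reset_index(drop=True)
    return dev, test
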