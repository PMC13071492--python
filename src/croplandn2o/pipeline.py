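"""End-to-end orchestration: synthetic data -> curation -> model ->
upscaling -> attribution -> scenarios, with a reproducibility manifest.

Every stochastic stage draws from an explicit named seed; re-running
with the same configuration reproduces identical artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import attribution, mlcore, obsdata, scenarios, schema, synthgen, upscale
from .errors import DependencyError, InputError, SchemaError, AlignmentError

logger = logging.getLogger(__name__)

STAGES = ("synth", "curate", "fit", "upscale", "attribute", "scenarios")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str = "runs/demo"
    stages: tuple[str, ...] = STAGES
    n_observations: int = 2186
    dev_fraction: float = 0.9
    grid_shape: tuple[int, int] = (20, 20)
    years: tuple[int, ...] = (2000, 2014, 2019)
    trend_spec: dict = field(default_factory=lambda: {
        "total_n_input": synthgen.Trend(1.3), "manure_ratio": synthgen.Trend(0.8)})
    model_family: str = "boosted_trees"
    model_grid: dict | None = None
    cv_folds: int = 10
    scenario_names: tuple[str, ...] = ("BAU", "HMR", "FMR", "HMR_MFE50", "FMR_MFE50")
    seeds: dict = field(default_factory=lambda: {
        "observations": 1, "grids": 2, "split": 3, "model": 4})

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InputError(f"unknown pipeline stages: {sorted(unknown)}")
        for stage in ("observations", "grids", "split", "model"):
            if stage not in self.seeds:
                raise InputError(f"missing seed for stochastic stage {stage!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trend = raw.pop("trend_spec", None)
        cfg = cls(**raw)
        if trend is not None:
            cfg.trend_spec = {k: synthgen.Trend(**v) for k, v in trend.items()}
        return cfg


@dataclass
class RunManifest:
    """Checksums and metadata of a completed (or failed) run."""

    config_hash: str
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> sha256
    completed_stages: list[str] = field(default_factory=list)
    failure: str | None = None
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    A failing stage leaves the artifacts of completed stages on disk
    and records the failure in the manifest.  Downstream stages that
    need a missing upstream artifact raise DependencyError naming it.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), started=time.time())

    def _save(name: str, path: Path) -> None:
        manifest.artifacts[name] = _sha256(path)

    table = truth = model = dev = test = series = None
    report_by_year: dict[int, upscale.AggregateReport] = {}
    try:
        if "synth" in config.stages:
            table, truth = synthgen.generate_observation_table(
                n=config.n_observations, seed=config.seeds["observations"])
            table.to_csv(out / "observations.csv", index=False)
            truth.to_json(out / "truth.json")
            _save("observations.csv", out / "observations.csv")
            _save("truth.json", out / "truth.json")
            manifest.completed_stages.append("synth")

        if "curate" in config.stages:
            if table is None:
                raise DependencyError("curate stage needs the synth stage output")
            screened, screen_report = obsdata.screen_records(table)
            screened = obsdata.derive_features(screened)
            screen_report.to_json(out / "screening.json")
            dev, test = obsdata.split_dev_test(
                screened, config.dev_fraction, seed=config.seeds["split"])
            dev.to_csv(out / "dev.csv", index=False)
            test.to_csv(out / "test.csv", index=False)
            for name in ("screening.json", "dev.csv", "test.csv"):
                _save(name, out / name)
            manifest.completed_stages.append("curate")

        if "fit" in config.stages:
            if dev is None:
                raise DependencyError("fit stage needs the curate stage output")
            spec = mlcore.ModelSpec(family=config.model_family,
                                    grid=config.model_grid,
                                    cv_folds=config.cv_folds,
                                    seed=config.seeds["model"])
            model = mlcore.tune_and_fit(dev, spec)
            metrics = mlcore.evaluate(model, test)
            importance = mlcore.relative_importance(model, dev)
            with open(out / "model.json", "w") as fh:
                json.dump({"family": model.family,
                           "hyperparams": model.hyperparams,
                           "cv_rmse": model.cv_rmse,
                           "metrics": asdict(metrics),
                           "seed": model.seed}, fh, indent=2)
            importance.to_csv(out / "importance.csv")
            _save("model.json", out / "model.json")
            _save("importance.csv", out / "importance.csv")
            manifest.completed_stages.append("fit")

        if "upscale" in config.stages:
            if model is None:
                raise DependencyError("upscale stage needs a fitted model")
            series = synthgen.generate_grid_series(
                years=list(config.years), trend_spec=config.trend_spec,
                seed=config.seeds["grids"],
                n_rows=config.grid_shape[0], n_cols=config.grid_shape[1])
            reports = upscale.series_losses(model, series)
            for year, rep in zip(series.years, reports):
                report_by_year[year] = rep
            with open(out / "losses.json", "w") as fh:
                json.dump({str(y): asdict(r) for y, r in report_by_year.items()},
                          fh, indent=2)
            schema.save_grid(series[series.years[-1]], out / "grid_final.nc")
            _save("losses.json", out / "losses.json")
            _save("grid_final.nc", out / "grid_final.nc")
            manifest.completed_stages.append("upscale")

        if "attribute" in config.stages:
            if model is None or series is None:
                raise DependencyError("attribute stage needs a fitted model "
                                      "and the upscale grid series")
            plan = attribution.FactorialPlan(t1=series.years[0], t2=series.years[-1])
            result = attribution.attribute_change(
                model, series[plan.t1], series[plan.t2], plan)
            result.to_json(out / "attribution.json")
            _save("attribution.json", out / "attribution.json")
            manifest.completed_stages.append("attribute")

        if "scenarios" in config.stages:
            if model is None or series is None:
                raise DependencyError("scenario stage needs a fitted model "
                                      "and the upscale grid series")
            base_grid = series[series.years[-1]]
            base_report = report_by_year[series.years[-1]]
            baseline_budget = scenarios.compute_budget(
                scenarios.PRESETS[scenarios.BASELINE_YEAR])
            out_scen = {}
            bau_report = None
            for name in config.scenario_names:
                budget = scenarios.compute_budget(scenarios.PRESETS[name])
                scales = scenarios.derive_scaling_factors(budget, baseline_budget)
                grid = scenarios.apply_scenario(base_grid, scales)
                rep = scenarios.project_and_compare(
                    model, grid, name, base_report, bau_report)
                if name == "BAU":
                    fg = upscale.predict_flux_grid(model, grid)
                    bau_report = upscale.aggregate_loss(fg, grid)
                out_scen[name] = asdict(rep)
            with open(out / "scenarios.json", "w") as fh:
                json.dump(out_scen, fh, indent=2)
            _save("scenarios.json", out / "scenarios.json")
            manifest.completed_stages.append("scenarios")
    except Exception as exc:  # noqa: BLE001 - recorded, then re-raised
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest.finished = time.time()
        manifest.to_json(out / "manifest.json")
        raise
    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    return manifest


@dataclass
class ValidationReport:
    passed: bool
    failures: list[str] = field(default_factory=list)


def validate_inputs(observation_csv=None, grid_paths=None) -> ValidationReport:
    """Schema and alignment checks for pipeline inputs.

    Failures are reported (never silently coerced): missing table
    columns are named, and grids that do not share a common shape are
    reported with both shapes.
    """
    failures: list[str] = []
    if observation_csv is not None:
        table = pd.read_csv(observation_csv)
        missing = [c for c in obsdata.REQUIRED_RAW_COLUMNS if c not in table.columns]
        if missing:
            failures.append(f"{observation_csv}: missing columns {missing}")
    grids = []
    for path in grid_paths or []:
        try:
            grids.append((path, schema.load_grid(path)))
        except (SchemaError, OSError) as exc:
            failures.append(f"{path}: {exc}")
    for (pa, ga), (pb, gb) in zip(grids, grids[1:]):
        try:
            schema.check_aligned(ga, gb)
        except AlignmentError as exc:
            failures.append(f"{pa} vs {pb}: {exc}")
    return ValidationReport(passed=not failures, failures=failures)
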