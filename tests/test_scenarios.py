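"""Nitrogen-budget engine: published-table reconstruction, scaling
factors, gridded application and relative-change reporting."""

import numpy as np
import pytest

from conftest import make_linear_model
from croplandn2o import scenarios, upscale
from croplandn2o.errors import ConfigError, InfeasibleScenarioError, InputError
from croplandn2o.scenarios import (PRESETS, ScalingFactors, ScenarioParams,
                                   apply_scenario, compute_budget,
                                   derive_scaling_factors, percent_change,
                                   round_half_up)


class TestRounding:
    def test_half_up_convention(self):
        assert round_half_up(11.985) == 11.99
        assert round_half_up(16.605) == 16.61
        assert round_half_up(24.9945) == 24.99
        assert round_half_up(1.005) == 1.01


class TestComputeBudget:
    def test_full_recycling_mfe50(self):
        b = compute_budget(PRESETS["FMR_MFE50"])
        r = b.rounded()
        assert r["available_manure_n_tg"] == 11.99
        assert r["available_chemical_n_tg"] == 16.61
        assert r["substitution_ratio_pct"] == 41.92
        assert r["total_available_n_tg"] == 28.59

    def test_baseline_year(self):
        b = compute_budget(PRESETS["2019"])
        r = b.rounded()
        assert r["total_manure_n_input_tg"] == 4.37
        assert r["substitution_ratio_pct"] == 5.39
        assert r["total_available_n_tg"] == 24.33

    def test_zero_recycling(self):
        p = ScenarioParams("null", 23.97, 0.0, 0.30,
                           total_available_n_target_tg=28.59)
        b = compute_budget(p)
        assert b.available_manure_n_tg == 0.0
        assert b.available_chemical_n_tg == 28.59
        assert b.substitution_ratio_pct == 0.0

    def test_available_n_conservation(self):
        """available chemical + available manure = target, exactly,
        for every feasible preset scenario."""
        for name in ("BAU", "HMR", "FMR", "HMR_MFE50", "FMR_MFE50"):
            b = compute_budget(PRESETS[name])
            assert b.available_chemical_n_tg + b.available_manure_n_tg \
                == pytest.approx(b.total_available_n_tg, abs=1e-12)

    def test_infeasible_budget_raises(self):
        p = ScenarioParams("toomuch", 200.0, 1.0, 0.5,
                           total_available_n_target_tg=28.59)
        with pytest.raises(InfeasibleScenarioError):
            compute_budget(p)

    def test_param_validation(self):
        with pytest.raises(ConfigError):
            ScenarioParams("bad", 10.0, 1.5, 0.3,
                           total_available_n_target_tg=20.0).validate()
        with pytest.raises(ConfigError):
            ScenarioParams("bad", 10.0, 0.5, 0.0,
                           total_available_n_target_tg=20.0).validate()
        with pytest.raises(ConfigError):
            ScenarioParams("bad", 10.0, 0.5, 0.3).validate()


class TestScalingFactors:
    def test_published_scales(self):
        baseline = compute_budget(PRESETS["2019"])
        fmr = derive_scaling_factors(compute_budget(PRESETS["FMR"]), baseline)
        assert round_half_up(fmr.manure_scale) == 5.49
        fmr50 = derive_scaling_factors(compute_budget(PRESETS["FMR_MFE50"]), baseline)
        assert round_half_up(fmr50.chemical_scale) == 0.72
        bau = derive_scaling_factors(compute_budget(PRESETS["BAU"]), baseline)
        assert round_half_up(bau.manure_scale) == 1.93

    def test_identity_scenario(self):
        baseline = compute_budget(PRESETS["2019"])
        s = derive_scaling_factors(baseline, baseline)
        assert (s.manure_scale, s.chemical_scale) == (1.0, 1.0)

    def test_budget_scale_consistency(self):
        """manure_scale x rounded baseline total = rounded scenario
        total, by construction."""
        baseline = compute_budget(PRESETS["2019"])
        for name in ("BAU", "HMR", "FMR"):
            b = compute_budget(PRESETS[name])
            s = derive_scaling_factors(b, baseline)
            assert s.manure_scale * round_half_up(baseline.total_manure_n_input_tg) \
                == pytest.approx(round_half_up(b.total_manure_n_input_tg))

    def test_zero_baseline_rejected(self):
        b = compute_budget(PRESETS["FMR"])
        zero = compute_budget(ScenarioParams(
            "z", 0.0, 1.0, 0.3, available_chemical_n_tg=0.0))
        with pytest.raises(InputError):
            derive_scaling_factors(b, zero)


class TestBudgetTable:
    def test_reconstruction_against_printed_cells(self):
        t = scenarios.budget_table()
        assert t.loc["2019", "total_manure_n_input_tg"] == 4.37
        assert t.loc["FMR_MFE50", "available_manure_n_tg"] == 11.99
        assert t.loc["FMR_MFE50", "available_chemical_n_tg"] == 16.61
        assert t.loc["FMR", "manure_scale"] == 5.49
        assert t.loc["FMR_MFE50", "chemical_scale"] == 0.72
        assert t.loc["BAU", "manure_scale"] == 1.93
        assert (t["total_available_n_tg"].loc[
            ["BAU", "HMR", "FMR", "HMR_MFE50", "FMR_MFE50"]] == 28.59).all()

    def test_mfe_monotonicity(self):
        """Raising MFE at a fixed target lowers the required chemical-N."""
        chems = []
        for mfe in (0.3, 0.4, 0.5):
            p = ScenarioParams("m", 23.97, 1.0, mfe,
                               total_available_n_target_tg=28.59)
            chems.append(compute_budget(p).available_chemical_n_tg)
        assert chems[0] > chems[1] > chems[2] >= 0


class TestApplyScenario:
    def test_identity_scales(self, toy_grid):
        out = apply_scenario(toy_grid, ScalingFactors(1.0, 1.0))
        for name in toy_grid.data_vars:
            np.testing.assert_array_equal(out[name].values,
                                          toy_grid[name].values)

    def test_uniform_scaling_linearity(self, small_grid):
        out = apply_scenario(small_grid, ScalingFactors(5.49, 0.72))
        area = small_grid["cropland_area"].values
        np.testing.assert_allclose(
            (out["ManN"].values * area).sum(),
            5.49 * (small_grid["ManN"].values * area).sum(), rtol=1e-12)

    def test_toy_cellwise_and_ratio_rises(self, toy_grid):
        out = apply_scenario(toy_grid, ScalingFactors(5.49, 0.72))
        np.testing.assert_allclose(out["CheN"].values,
                                   0.72 * toy_grid["CheN"].values)
        np.testing.assert_allclose(out["ManN"].values,
                                   5.49 * toy_grid["ManN"].values)
        old_total = toy_grid["CheN"].values + toy_grid["ManN"].values
        has_both = (toy_grid["ManN"].values > 0) & (toy_grid["CheN"].values > 0)
        new_total = out["CheN"].values + out["ManN"].values
        old_r = np.divide(toy_grid["ManN"].values, old_total,
                          out=np.zeros_like(old_total), where=old_total > 0)
        new_r = np.divide(out["ManN"].values, new_total,
                          out=np.zeros_like(new_total), where=new_total > 0)
        assert (new_r[has_both] > old_r[has_both]).all()

    def test_climate_and_cropland_replacement(self, toy_grid):
        future = toy_grid.copy(deep=True)
        future["MAT"] = toy_grid["MAT"] + 1.5
        future["cropland_area"] = toy_grid["cropland_area"] * 0.9
        out = apply_scenario(toy_grid, ScalingFactors(1.0, 1.0),
                             climate=future, cropland=future)
        np.testing.assert_array_equal(out["MAT"].values, future["MAT"].values)
        np.testing.assert_array_equal(out["cropland_area"].values,
                                      future["cropland_area"].values)
        # soil layers untouched
        np.testing.assert_array_equal(out["SOM"].values, toy_grid["SOM"].values)


class TestProjection:
    def test_printed_relative_change_identities(self):
        """The delta formulas reproduce the published relative changes
        from the published national totals."""
        assert percent_change(287.3, 243.7) == pytest.approx(17.9, abs=0.05)
        assert percent_change(222.0, 287.3) == pytest.approx(-22.7, abs=0.05)
        assert percent_change(233.5, 256.5) == pytest.approx(-9.0, abs=0.05)

    def test_identity_grid_zero_deltas(self, small_grid):
        model = make_linear_model({"CheN": 0.01}, intercept=0.5)
        fg = upscale.predict_flux_grid(model, small_grid)
        base = upscale.aggregate_loss(fg, small_grid)
        rep = scenarios.project_and_compare(model, small_grid, "same",
                                            base, base)
        assert rep.delta_vs_baseline_pct == pytest.approx(0.0, abs=1e-12)
        assert rep.delta_vs_bau_pct == pytest.approx(0.0, abs=1e-12)

    def test_zero_reference_undefined(self):
        with pytest.raises(InputError):
            percent_change(10.0, 0.0)
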