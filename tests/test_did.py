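import logging

import numpy as np
import pandas as pd
import pytest

from invadeloss import (
    annual_losses,
    build_panel,
    counterfactual_outputs,
    fit_staggered_did,
)
from invadeloss.did import StaggeredDID
from invadeloss.errors import IdentificationError, InputError
from invadeloss.synth import SpreadSchedule


def two_by_two():
    """Classic 2x2 panel: unit 2 treated in year 2, effect -3."""
    return pd.DataFrame({
        "unit": [1, 1, 2, 2],
        "year": [1, 2, 1, 2],
        "y": [10.0, 10.0, 10.0, 7.0],
        "D": [0, 0, 0, 1],
    })


def within_transform_beta(panel):
    """Oracle: double-demeaning FE estimator on a balanced panel."""
    df = panel.copy()
    for col in ("y", "x"):
        df[col + "_dm"] = (df[col]
                           - df.groupby("unit")[col].transform("mean")
                           - df.groupby("year")[col].transform("mean")
                           + df[col].mean())
    num = (df["y_dm"] * df["x_dm"]).sum()
    den = (df["x_dm"] ** 2).sum()
    return num / den


class TestBuildPanel:
    def outputs(self):
        rows = [(u, t, "forestry", 10.0) for u in (1, 2, 3)
                for t in range(2011, 2017)]
        return pd.DataFrame(rows, columns=["unit", "year", "sector", "value"])

    def test_never_infested_unit_all_zero(self):
        sched = SpreadSchedule({1: 2013, 2: None, 3: 2015})
        panel = build_panel(self.outputs(), sched)
        assert (panel[panel["unit"] == 2]["D"] == 0).all()

    def test_threshold_rule(self):
        sched = SpreadSchedule({1: 2014, 2: None, 3: None})
        panel = build_panel(self.outputs(), sched)
        d = panel[panel["unit"] == 1].sort_values("year")["D"].tolist()
        assert d == [0, 0, 0, 1, 1, 1]

    def test_missing_schedule_unit_rejected(self):
        with pytest.raises(InputError):
            build_panel(self.outputs(), SpreadSchedule({1: 2013}))

    def test_estimable_without_controls(self):
        sched = SpreadSchedule({1: 2013, 2: None, 3: None})
        panel = build_panel(self.outputs(), sched)
        fit = fit_staggered_did(panel, cov_type="HC1")
        assert np.isfinite(fit.beta)


class TestFitStaggeredDID:
    def test_two_by_two_identity(self):
        fit = fit_staggered_did(two_by_two(), cov_type="HC1")
        assert fit.beta == pytest.approx(-3.0, abs=1e-10)

    def test_zero_beta_noiseless(self, noiseless_panel):
        panel, truth = noiseless_panel
        sub = panel[panel["sector"] == "husbandry"].copy()
        # strip the planted effect so the true beta is exactly zero
        sub["y"] = sub["y"] - truth["beta"]["husbandry"] * sub["exposure"] * sub["D"]
        fit = fit_staggered_did(sub, controls=("w_climate",),
                                exposure_col="exposure")
        assert fit.beta == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_staggered_recovery_exact(self, noiseless_panel):
        panel, truth = noiseless_panel
        sub = panel[panel["sector"] == "forestry"]
        fit = fit_staggered_did(sub, controls=("w_climate",),
                                exposure_col="exposure")
        assert fit.beta == pytest.approx(truth["beta"]["forestry"], abs=1e-8)
        assert fit.theta["w_climate"] == pytest.approx(truth["theta"],
                                                       abs=1e-8)
        assert fit.alpha == pytest.approx(truth["alpha"]["forestry"],
                                          abs=1e-8)
        for u, mu in truth["mu"].items():
            assert fit.unit_effects[u] == pytest.approx(mu, abs=1e-8)
        for t, ga in truth["gamma"].items():
            assert fit.year_effects[t] == pytest.approx(ga, abs=1e-8)

    def test_agrees_with_within_transform_oracle(self, rng):
        units, years = range(1, 13), range(2011, 2019)
        rows = []
        for u in units:
            fy = 2013 + (u % 4)
            for t in years:
                d = int(u <= 8 and t >= fy)
                rows.append((u, t, 5.0 + 0.5 * u - 0.2 * t
                             - 2.0 * d + rng.normal(0, 0.3), d))
        panel = pd.DataFrame(rows, columns=["unit", "year", "y", "D"])
        panel["x"] = panel["D"].astype(float)
        fit = fit_staggered_did(panel)
        assert fit.beta == pytest.approx(within_transform_beta(panel),
                                         abs=1e-8)

    def test_residuals_sum_to_zero_and_t_is_beta_over_se(self, rng):
        panel = pd.DataFrame({
            "unit": np.repeat(np.arange(10), 6),
            "year": np.tile(np.arange(2011, 2017), 10),
        })
        panel["D"] = ((panel["unit"] >= 5)
                      & (panel["year"] >= 2014)).astype(int)
        panel["y"] = rng.normal(10, 1, len(panel)) - 2.0 * panel["D"]
        fit = fit_staggered_did(panel)
        assert abs(fit.residuals.sum()) < 1e-8
        assert fit.tstat == pytest.approx(fit.beta / fit.se, rel=1e-10)

    @pytest.mark.parametrize("d_all", [0, 1])
    def test_degenerate_treatment_rejected(self, d_all):
        panel = two_by_two()
        panel["D"] = d_all
        with pytest.raises(IdentificationError):
            fit_staggered_did(panel)

    def test_single_unit_or_year_rejected(self):
        single_unit = pd.DataFrame({"unit": [1, 1], "year": [1, 2],
                                    "y": [1.0, 2.0], "D": [0, 1]})
        with pytest.raises(IdentificationError):
            fit_staggered_did(single_unit)

    def test_duplicate_observations_rejected(self):
        panel = two_by_two()
        panel.loc[1, "year"] = 1
        with pytest.raises(InputError):
            fit_staggered_did(panel)

    def test_collinear_control_dropped_with_warning(self, caplog):
        panel = two_by_two()
        panel["w_dup"] = panel["D"].astype(float)  # collinear with treatment
        with caplog.at_level(logging.WARNING):
            fit = fit_staggered_did(panel, controls=("w_dup",),
                                    cov_type="HC1")
        assert "collinear" in caplog.text
        assert "w_dup" not in fit.theta
        assert fit.beta == pytest.approx(-3.0, abs=1e-10)

    def test_estimator_params_roundtrip(self):
        est = StaggeredDID(controls=("w",), cov_type="HC1")
        assert est.get_params()["cov_type"] == "HC1"


class TestCounterfactual:
    def test_untreated_equals_observed(self):
        fit = fit_staggered_did(two_by_two(), cov_type="HC1")
        cf = counterfactual_outputs(fit, two_by_two())
        untreated = cf[cf["D"] == 0]
        np.testing.assert_allclose(untreated["counterfactual"],
                                   untreated["y"])

    def test_treated_shifted_by_minus_beta(self):
        fit = fit_staggered_did(two_by_two(), cov_type="HC1")
        cf = counterfactual_outputs(fit, two_by_two())
        treated = cf[cf["D"] == 1].iloc[0]
        assert treated["counterfactual"] == pytest.approx(
            treated["y"] + 3.0, abs=1e-10)

    def test_zero_beta_is_identity(self):
        panel = two_by_two()
        panel["y"] = 10.0  # no effect anywhere
        fit = fit_staggered_did(panel, cov_type="HC1")
        cf = counterfactual_outputs(fit, panel)
        np.testing.assert_allclose(cf["counterfactual"], cf["y"],
                                   atol=1e-10)


class TestAnnualLosses:
    def cf_panel(self):
        df = two_by_two()
        df["sector"] = "forestry"
        fit = fit_staggered_did(df, cov_type="HC1")
        return counterfactual_outputs(fit, df)

    def test_unit_deflator_gives_nominal_losses(self):
        losses = annual_losses(self.cf_panel(), {1: 1.0, 2: 1.0})
        year2 = losses[losses["year"] == 2].iloc[0]
        assert year2["loss"] == pytest.approx(3.0, abs=1e-10)

    def test_deflator_divides_gap(self):
        losses = annual_losses(self.cf_panel(), {1: 1.0, 2: 1.5})
        year2 = losses[losses["year"] == 2].iloc[0]
        assert year2["loss"] == pytest.approx(2.0, abs=1e-10)

    def test_zero_beta_zero_losses(self):
        df = two_by_two()
        df["y"] = 10.0
        fit = fit_staggered_did(df, cov_type="HC1")
        losses = annual_losses(counterfactual_outputs(fit, df))
        np.testing.assert_allclose(losses["loss"], 0.0, atol=1e-9)

    def test_missing_deflator_year_rejected(self):
        with pytest.raises(InputError):
            annual_losses(self.cf_panel(), {1: 1.0})

    def test_cumulative_is_running_sum(self):
        losses = annual_losses(self.cf_panel())
        np.testing.assert_allclose(losses["cumulative_loss"],
                                   losses["loss"].cumsum())
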