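"""Monte-Carlo design-space risk: coefficient sampling, the analytic normal
oracle, map structure and the lexicographic green selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import greenflow as gf
from greenflow import risk, rsm


def _const_model(prediction: float, var: float = 0.0) -> rsm.QuadraticModel:
    """Intercept-only model predicting ``prediction`` with coefficient variance ``var``."""
    return rsm.QuadraticModel(
        terms=[rsm.ModelTerm("intercept")],
        coefficients=np.array([prediction]),
        coef_covariance=np.array([[var]]),
        sigma2=0.0,
        R2=1.0,
        R2_adj=1.0,
        CV_percent=0.0,
        SD=0.0,
        anova=pd.DataFrame([{"term": "Model", "F": np.inf, "p": 0.0}]),
        n_obs=15,
    )


class TestDrawCoefficients:
    def test_zero_covariance_draws_equal_estimates(self, fitted_model):
        model = _const_model(0.6, var=0.0)
        draws = gf.draw_coefficients(model, 50, seed=0)
        assert np.allclose(draws, 0.6)

    def test_same_seed_identical(self, fitted_model):
        a = gf.draw_coefficients(fitted_model, 100, seed=9)
        b = gf.draw_coefficients(fitted_model, 100, seed=9)
        assert np.array_equal(a, b)

    def test_sample_mean_near_estimates(self, fitted_model):
        draws = gf.draw_coefficients(fitted_model, 10_000, seed=1)
        se = np.sqrt(np.diag(fitted_model.coef_covariance))
        assert np.all(np.abs(draws.mean(axis=0) - fitted_model.coefficients) < 3 * se / np.sqrt(10_000) + 1e-12)

    def test_non_psd_covariance_rejected(self):
        model = _const_model(0.6)
        model.coef_covariance = np.array([[-1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            gf.draw_coefficients(model, 10, seed=0)


class TestRiskAtPoint:
    def test_certain_in_band_prediction_has_zero_risk(self):
        settings = gf.RiskSettings(seed=0)
        assert gf.risk_at_point(_const_model(0.60), np.zeros(4), settings) == 0.0

    def test_certain_out_of_band_prediction_has_unit_risk(self):
        settings = gf.RiskSettings(seed=0)
        assert gf.risk_at_point(_const_model(0.90), np.zeros(4), settings) == 1.0

    @pytest.mark.parametrize("mu,sd", [(0.60, 0.03), (0.56, 0.02), (0.68, 0.05)])
    def test_matches_closed_form_normal_tail(self, mu, sd):
        """MC risk within 3 binomial SEs of the exact normal tail probability."""
        settings = gf.RiskSettings(n_sims=500, seed=4)
        exact = stats.norm.cdf(0.55, mu, sd) + stats.norm.sf(0.70, mu, sd)
        mc = gf.risk_at_point(_const_model(mu, var=sd**2), np.zeros(4), settings)
        tol = 3 * np.sqrt(exact * (1 - exact) / 500)
        assert abs(mc - exact) <= tol

    def test_estimate_spread_shrinks_with_more_simulations(self):
        model = _const_model(0.56, var=0.02**2)
        spreads = []
        for n_sims in (200, 3200):  # 16x simulations -> ~4x smaller SD
            ests = [
                gf.risk_at_point(model, np.zeros(4), gf.RiskSettings(n_sims=n_sims, seed=s))
                for s in range(40)
            ]
            spreads.append(np.std(ests))
        assert spreads[1] < spreads[0] / 2


class TestRiskMap:
    def test_uniformly_safe_model_is_all_feasible(self, factors):
        grid = risk.GridSpec.from_factors(factors, steps={"temperature": 10, "time": 5, "mass_fraction": 0.1, "alkali": 0.007})
        rm = gf.exhaustive_risk_map(_const_model(0.6), grid, gf.RiskSettings(seed=0), factors)
        assert rm.table["feasible"].all()
        assert np.all(rm.table["risk"] == 0.0)

    def test_uniformly_unsafe_model_is_all_infeasible(self, factors):
        grid = risk.GridSpec.from_factors(factors, steps={"temperature": 10, "time": 5, "mass_fraction": 0.1, "alkali": 0.007})
        rm = gf.exhaustive_risk_map(_const_model(0.9), grid, gf.RiskSettings(seed=0), factors)
        assert not rm.table["feasible"].any()

    def test_feasible_set_grows_with_acceptable_risk(self, fitted_model, factors):
        grid = risk.GridSpec.from_factors(factors, steps={"temperature": 5, "time": 5, "mass_fraction": 0.05, "alkali": 0.007})
        n_feas = []
        for acc in (0.05, 0.2, 0.5):
            rm = gf.exhaustive_risk_map(
                fitted_model, grid, gf.RiskSettings(acceptable_risk=acc, seed=3), factors
            )
            n_feas.append(int(rm.table["feasible"].sum()))
        assert n_feas[0] <= n_feas[1] <= n_feas[2]

    def test_empty_grid_rejected(self, fitted_model, factors):
        with pytest.raises(ValueError):
            risk.GridSpec(levels={"temperature": np.array([])})


def _toy_map(w_levels, feasible_w):
    rows = []
    for w in w_levels:
        rows.append(
            {
                "temperature": 70.0,
                "time": 5.0,
                "mass_fraction": w,
                "alkali": 0.116,
                "risk": 0.1 if w in feasible_w else 0.9,
                "feasible": w in feasible_w,
            }
        )
    return risk.RiskMap(table=pd.DataFrame(rows), settings=gf.RiskSettings())


class TestSelectConditions:
    def test_margin_rule_picks_central_mass_fraction(self):
        levels = [0.15, 0.20, 0.25, 0.30, 0.35]
        sel = gf.select_conditions(_toy_map(levels, feasible_w={0.20, 0.25, 0.30}))
        assert sel.wi == 0.25
        assert (sel.T, sel.t0, sel.lam_a) == (70.0, 5.0, 0.116)

    def test_single_feasible_point_is_returned(self):
        sel = gf.select_conditions(_toy_map([0.15, 0.25, 0.35], feasible_w={0.25}))
        assert sel.wi == 0.25

    def test_all_infeasible_raises_no_design_space(self):
        with pytest.raises(ValueError, match="no design space"):
            gf.select_conditions(_toy_map([0.15, 0.25], feasible_w=set()))

    def test_one_sided_band_selects_interior_point(self):
        # feasible only at the low end: margin vs the uncertified region below
        # and the infeasible region above favours the middle of the band
        levels = [0.15, 0.20, 0.25, 0.30, 0.35]
        sel = gf.select_conditions(_toy_map(levels, feasible_w={0.15, 0.20, 0.25}))
        assert sel.wi == 0.20

    def test_lexicographic_priorities(self, fitted_model, factors):
        grid = risk.GridSpec.from_factors(factors, steps={"temperature": 5, "time": 5, "mass_fraction": 0.05, "alkali": 0.007})
        rm = gf.exhaustive_risk_map(fitted_model, grid, gf.RiskSettings(seed=3), factors)
        sel = gf.select_conditions(rm)
        feas = rm.feasible
        assert sel.lam_a == feas["alkali"].min()
        sub = feas[np.isclose(feas["alkali"], sel.lam_a)]
        assert sel.t0 == sub["time"].min()
        sub = sub[np.isclose(sub["time"], sel.t0)]
        assert sel.T == sub["temperature"].min()
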