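"""Quadratic response-surface fitting, ANOVA and backward elimination,
cross-checked against statsmodels OLS and closed-form F identities."""

import numpy as np
import pytest
import statsmodels.api as sm

import greenflow as gf
from greenflow import rsm

NAMES = ("temperature", "time", "mass_fraction", "alkali")


def _random_coded(n, rng):
    return rng.choice([-1.0, 0.0, 1.0], size=(n, 4))


class TestModelMatrix:
    def test_center_run_row(self):
        terms = rsm.full_quadratic_terms(4)
        row = rsm.build_model_matrix(np.zeros((1, 4)), terms)
        assert row[0, 0] == 1.0
        assert np.all(row[0, 1:] == 0.0)

    def test_full_quadratic_has_15_columns(self):
        terms = rsm.full_quadratic_terms(4)
        assert len(terms) == 15  # 1 + 4 + 4 + 6
        x = rsm.build_model_matrix(np.ones((3, 4)), terms)
        assert x.shape == (3, 15)

    def test_interaction_entry_vanishes_when_either_factor_is_zero(self):
        term = rsm.ModelTerm("interaction", (0, 2))  # temperature x mass fraction
        x = rsm.build_model_matrix(np.array([[-1.0, -1.0, 0.0, 1.0]]), [term])
        assert x[0, 0] == 0.0

    def test_malformed_terms_rejected(self):
        with pytest.raises(ValueError):
            rsm.ModelTerm("cubic", (0,))
        with pytest.raises(ValueError):
            rsm.ModelTerm("interaction", (1, 1))


class TestFitQuadratic:
    def test_noise_free_coefficients_recovered_exactly(self, design):
        terms = [
            rsm.ModelTerm("intercept"),
            rsm.ModelTerm("linear", (0,)),
            rsm.ModelTerm("linear", (2,)),
            rsm.ModelTerm("interaction", (0, 2)),
        ]
        truth = np.array([0.7, 0.05, 0.1, -0.04])
        y = rsm.build_model_matrix(design.coded, terms) @ truth
        model = rsm.fit_quadratic(design.coded, y, terms)
        assert np.allclose(model.coefficients, truth, atol=1e-9)

    def test_saturated_noise_free_fit_is_exact(self):
        # one factor at its three levels, full quadratic: exact interpolation
        rng = np.random.default_rng(0)
        coded = np.array([[-1.0], [0.0], [1.0]])
        terms = [rsm.ModelTerm("intercept"), rsm.ModelTerm("linear", (0,)), rsm.ModelTerm("quadratic", (0,))]
        y = rng.normal(size=3)
        model = rsm.fit_quadratic(coded, y, terms, factor_names=("x",))
        assert model.R2 == pytest.approx(1.0)
        assert np.allclose(rsm.build_model_matrix(coded, terms) @ model.coefficients, y)

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(42)
        coded = _random_coded(40, rng)
        terms = rsm.full_quadratic_terms(4)
        x = rsm.build_model_matrix(coded, terms)
        y = x @ rng.normal(size=15) + rng.normal(0, 0.05, size=40)
        model = rsm.fit_quadratic(coded, y, terms)
        ref = sm.OLS(y, x).fit()
        assert np.allclose(model.coefficients, ref.params, atol=1e-8)
        assert np.allclose(model.coef_covariance, ref.cov_params(), atol=1e-8)
        assert model.R2 == pytest.approx(ref.rsquared)
        assert model.R2_adj == pytest.approx(ref.rsquared_adj)
        # drop-one partial F for a single column equals the squared t statistic
        for k, t in enumerate(terms):
            if t.kind == "intercept":
                continue
            f_ours = float(model.anova.loc[model.anova["term"] == t.label(NAMES), "F"].iloc[0])
            assert f_ours == pytest.approx(ref.tvalues[k] ** 2, rel=1e-8)
        f_model = float(model.anova.loc[model.anova["term"] == "Model", "F"].iloc[0])
        assert f_model == pytest.approx(ref.fvalue, rel=1e-8)

    def test_whole_model_f_consistent_with_r2(self):
        rng = np.random.default_rng(3)
        coded = _random_coded(20, rng)
        terms = rsm.full_quadratic_terms(4)[:5]
        y = coded[:, 0] * 0.3 + rng.normal(0, 0.1, 20)
        model = rsm.fit_quadratic(coded, y, terms)
        p = 4  # non-intercept terms
        n = 20
        f_from_r2 = (model.R2 / p) / ((1 - model.R2) / (n - p - 1))
        f_model = float(model.anova.loc[model.anova["term"] == "Model", "F"].iloc[0])
        assert f_model == pytest.approx(f_from_r2, rel=1e-10)

    def test_rank_deficiency_names_aliased_terms(self):
        coded = np.zeros((10, 4))
        coded[:, 0] = np.tile([-1.0, 1.0], 5)
        coded[:, 1] = coded[:, 0]  # time column duplicates temperature
        terms = rsm.full_quadratic_terms(4)[:3]  # intercept + two linear terms
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            rsm.fit_quadratic(coded, np.arange(10.0), terms)

    def test_duplicate_terms_rejected(self, design):
        terms = [rsm.ModelTerm("intercept"), rsm.ModelTerm("linear", (0,)), rsm.ModelTerm("linear", (0,))]
        with pytest.raises(ValueError, match="duplicate"):
            rsm.fit_quadratic(design.coded, np.arange(15.0), terms)


class TestBackwardElimination:
    def test_hierarchy_forces_linear_parents(self, design):
        # response driven purely by the T x w interaction; its parent linear
        # terms are insignificant yet must survive while the interaction does
        rng = np.random.default_rng(1)
        inter = design.coded[:, 0] * design.coded[:, 2]
        y = 0.7 + 0.3 * inter + rng.normal(0, 0.01, 15)
        terms = [
            rsm.ModelTerm("intercept"),
            rsm.ModelTerm("linear", (0,)),
            rsm.ModelTerm("linear", (1,)),
            rsm.ModelTerm("linear", (2,)),
            rsm.ModelTerm("linear", (3,)),
            rsm.ModelTerm("interaction", (0, 2)),
        ]
        model = gf.backward_eliminate(design.coded, y, terms=terms, alpha=0.10)
        labels = {t.label(NAMES) for t in model.terms}
        assert "temperature*mass_fraction" in labels
        assert {"temperature", "mass_fraction"} <= labels
        assert model.term_pvalue(rsm.ModelTerm("linear", (0,))) > 0.10  # kept by hierarchy alone

    def test_heredity_start_recovers_interaction_with_active_parents(self, design):
        # over-parameterised start (full quadratic on a 13-point design):
        # staged reduction keeps the true second-order term of active parents
        rng = np.random.default_rng(2)
        truth = gf.default_truth()
        y = truth.evaluate(design.coded) + rng.normal(0, 0.01, 15)
        model = gf.backward_eliminate(design.coded, y, alpha=0.10)
        labels = {t.label(NAMES) for t in model.terms}
        assert {"temperature", "time", "mass_fraction", "temperature*mass_fraction"} <= labels
        assert "alkali" not in labels

    def test_pure_noise_strips_most_terms(self, design):
        retained = []
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            y = rng.normal(0.7, 0.045, 15)
            model = gf.backward_eliminate(design.coded, y, alpha=0.10)
            retained.append(sum(1 for t in model.terms if t.kind != "intercept"))
        # with alpha=0.10 the expected surviving count is small, not ~14
        assert np.mean(retained) < 4.0

    def test_removing_terms_never_leaves_insignificant_eligible(self, campaign_xy):
        coded, y = campaign_xy
        model = gf.backward_eliminate(coded, y, alpha=0.10)
        protected = {
            i for t in model.terms if t.kind in ("quadratic", "interaction") for i in t.indices
        }
        for t in model.terms:
            if t.kind == "intercept" or (t.kind == "linear" and t.indices[0] in protected):
                continue
            assert model.term_pvalue(t) <= 0.10

    def test_r2adj_bounded_by_r2_and_r2_monotone_under_removal(self, campaign_xy):
        coded, y = campaign_xy
        full_terms = rsm.full_quadratic_terms(4)[:9]  # intercept + linear + quadratic
        model_full = rsm.fit_quadratic(coded, y, full_terms)
        model_red = rsm.fit_quadratic(coded, y, full_terms[:-1])
        assert model_full.R2_adj <= model_full.R2
        assert model_red.R2 <= model_full.R2 + 1e-12


class TestPredict:
    def test_intercept_only_model(self):
        rng = np.random.default_rng(2)
        coded = np.zeros((12, 4))
        y = rng.normal(0.7, 0.05, 12)
        model = rsm.fit_quadratic(coded, y, [rsm.ModelTerm("intercept")])
        mean, se = rsm.predict(model, np.zeros(4), with_uncertainty=True)
        assert mean == pytest.approx(y.mean())
        assert se == pytest.approx(np.sqrt(model.sigma2 / 12))

    def test_noise_free_model_has_zero_se(self, design):
        terms = rsm.full_quadratic_terms(4)[:5]
        y = rsm.build_model_matrix(design.coded, terms) @ np.array([0.7, 0.05, 0.04, 0.1, 0.0])
        model = rsm.fit_quadratic(design.coded, y, terms)
        _, se = rsm.predict(model, [1, 1, 1, 1], with_uncertainty=True)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_matrix_arithmetic(self, fitted_model):
        x0 = np.array([-1.0, -1.0, 0.0, 0.0])
        xrow = rsm.build_model_matrix(x0[None, :], fitted_model.terms)[0]
        mean, se = rsm.predict(fitted_model, x0, with_uncertainty=True)
        assert mean == pytest.approx(float(xrow @ fitted_model.coefficients))
        assert se == pytest.approx(float(np.sqrt(xrow @ fitted_model.coef_covariance @ xrow)))


def test_model_json_round_trip(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    fitted_model.to_json(path)
    import json

    back = rsm.QuadraticModel.from_dict(json.loads(path.read_text()))
    assert back.terms == fitted_model.terms
    assert np.allclose(back.coefficients, fitted_model.coefficients)
    assert np.allclose(back.coef_covariance, fitted_model.coef_covariance)
    assert back.R2 == pytest.approx(fitted_model.R2)
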