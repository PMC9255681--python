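"""Penalised/unpenalised weighted logistic fits and Bolasso selection."""

import math

import numpy as np
import pandas as pd
import pytest

import fallrisk as fr
from fallrisk.model import (
    BolassoConfig,
    DegenerateOutcomeError,
    FinalModel,
    ModelError,
    lambda_grid,
)
from conftest import toy_logistic


def _two_by_two():
    """30/100 events among exposed, 10/100 among unexposed."""
    x = np.repeat([1.0, 0.0], 100)
    y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
    return pd.DataFrame({"exposed": x}), y


class TestWeightedLogistic:
    def test_matches_closed_form_log_odds_ratio(self):
        X, y = _two_by_two()
        m = fr.fit_weighted_logistic(X, y)
        assert m.coef[0] == pytest.approx(math.log((30 * 90) / (10 * 70)), abs=1e-6)
        assert m.coef[0] == pytest.approx(1.3499, abs=1e-4)
        assert m.converged

    def test_constant_outcome_raises(self):
        X, _ = _two_by_two()
        with pytest.raises(DegenerateOutcomeError):
            fr.fit_weighted_logistic(X, np.ones(len(X)))

    def test_halved_weights_keep_coefficients_and_widen_cis(self):
        X, y = toy_logistic(n=1500, p=3, beta=[0.8, -0.5, 0.0], seed=2)
        w = np.random.default_rng(0).uniform(0.5, 1.0, len(y))
        full = fr.fit_weighted_logistic(X, y, w)
        half = fr.fit_weighted_logistic(X, y, w / 2)
        np.testing.assert_allclose(half.coef, full.coef, atol=1e-6)
        np.testing.assert_allclose(half.se, full.se * math.sqrt(2), rtol=1e-4)
        assert (half.ci_high - half.ci_low > full.ci_high - full.ci_low).all()

    def test_or_equals_exp_coefficient(self):
        X, y = _two_by_two()
        m = fr.fit_weighted_logistic(X, y)
        np.testing.assert_allclose(m.odds_ratios, np.exp(m.coef), rtol=1e-12)
        lo, hi = m.or_ci
        assert lo[0] <= m.odds_ratios[0] <= hi[0]

    def test_separation_is_flagged_not_silent(self):
        X = pd.DataFrame({"x": np.repeat([0.0, 1.0], 20)})
        y = X["x"].to_numpy().copy()
        m = fr.fit_weighted_logistic(X, y)
        assert not m.converged

    def test_json_round_trip(self, tmp_path):
        X, y = _two_by_two()
        m = fr.fit_weighted_logistic(X, y)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = FinalModel.from_json(path)
        assert back.names == m.names
        np.testing.assert_allclose(back.coef, m.coef)
        np.testing.assert_allclose(back.se, m.se)


class TestLasso:
    def test_full_shrinkage_above_lambda_max(self):
        X, y = toy_logistic(n=800, p=6, beta=[1.0, -1.0, 0, 0, 0, 0], seed=3)
        Xs = (X - X.mean()) / X.std(ddof=0)
        lam_max = lambda_grid(Xs.to_numpy(), y, np.ones(len(y)), 5, 0.1)[0]
        b0, coefs, _ = fr.lasso_logistic_path(X, y, lambdas=[lam_max * 1.01])
        assert (coefs.iloc[0] == 0).all()

    def test_zero_penalty_limit_matches_unpenalised_fit(self):
        X, y = toy_logistic(n=600, p=5, beta=[1.2, -0.8, 0.5, 0, 0], seed=4)
        w = np.random.default_rng(1).uniform(0.3, 1.0, len(y))
        b0, coefs, conv = fr.lasso_logistic_path(X, y, w, lambdas=[1e-10], tol=1e-9)
        m = fr.fit_weighted_logistic(X, y, w)
        assert conv[0]
        np.testing.assert_allclose(coefs.iloc[0].to_numpy(), m.coef, atol=1e-6)
        assert b0[0] == pytest.approx(m.intercept, abs=1e-6)

    def test_strong_predictor_always_enters_at_cv_min(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            X, y = toy_logistic(n=5000, p=5, beta=[1.5, 0, 0, 0, 0], seed=100 + rep)
            fit = fr.fit_lasso_logistic(X, y, config=BolassoConfig(seed=rep, nlambda=20))
            hits += "x0" in fit.active
        assert hits == reps

    def test_zero_variance_matrix_warns_empty(self):
        X = pd.DataFrame({"a": np.zeros(50), "b": np.ones(50)})
        y = np.tile([0.0, 1.0], 25)
        with pytest.warns(UserWarning, match="zero variance"):
            fit = fr.fit_lasso_logistic(X, y)
        assert fit.active == []


class TestBolasso:
    def test_config_validation(self):
        with pytest.raises(ModelError):
            BolassoConfig(n_bootstrap=0)
        with pytest.raises(ModelError):
            BolassoConfig(threshold=1.2)
        with pytest.raises(ModelError):
            BolassoConfig(lambda_rule="aic")

    def test_pure_noise_selects_nothing_at_full_consistency(self):
        X, y = toy_logistic(n=2000, p=20, beta=None, intercept=-1.5, seed=6)
        sel = fr.run_bolasso(X, y, config=BolassoConfig(n_bootstrap=25, seed=6, nlambda=20))
        assert sel.selected(1.0) == []

    def test_threshold_monotonicity(self, small_design):
        sel = fr.run_bolasso(
            small_design.X, small_design.y.to_numpy(), small_design.w.to_numpy(),
            BolassoConfig(n_bootstrap=8, inner_cv_folds=4, nlambda=15, seed=1),
        )
        assert set(sel.selected(1.0)) <= set(sel.selected(0.8))
        assert ((sel.frequencies >= 0) & (sel.frequencies <= 1)).all()

    def test_deterministic_and_column_order_invariant(self):
        X, y = toy_logistic(n=1200, p=8, beta=[1.0, -0.9, 0, 0, 0, 0, 0, 0], seed=7)
        cfg = BolassoConfig(n_bootstrap=10, inner_cv_folds=4, nlambda=15, seed=9)
        a = fr.run_bolasso(X, y, config=cfg)
        b = fr.run_bolasso(X, y, config=cfg)
        pd.testing.assert_series_equal(a.frequencies, b.frequencies)
        perm = list(reversed(X.columns))
        c = fr.run_bolasso(X[perm], y, config=cfg)
        pd.testing.assert_series_equal(
            a.frequencies.sort_index(), c.frequencies.sort_index()
        )


class TestPrediction:
    def _printed_model(self):
        names = [
            "age", "female_sex", "history_of_falls", "proton_pump_inhibitors",
            "opioids", "previous_injury", "depression", "osteoarthritis",
            "urinary_incontinence", "memory_concentration_problems",
        ]
        coef = np.array([0.06, 0.26, 0.72, 0.29, 0.24, 0.35, 0.54, 0.20, 0.36, 0.41])
        nan = np.full(10, np.nan)
        return FinalModel(names, -6.92, coef, np.full(11, np.nan), nan, nan, True, 0)

    def test_sigmoid_symmetry_at_zero_lp(self):
        m = FinalModel(["x"], 0.0, np.array([1.0]), np.full(2, np.nan),
                       np.array([np.nan]), np.array([np.nan]), True, 0)
        row = pd.DataFrame({"x": [0.0]})
        assert fr.predict_probability(m, row)[0] == 0.5

    def test_published_linear_predictor_example(self):
        # 75-year-old woman with a fall history, nothing else:
        # LP = -6.92 + 0.06*75 + 0.26 + 0.72 = -1.44 -> p ~ 0.1916
        m = self._printed_model()
        row = pd.DataFrame(
            {n: [0.0] for n in m.names} | {"age": [75.0], "female_sex": [1.0],
                                           "history_of_falls": [1.0]}
        )
        lp = m.linear_predictor(row)[0]
        assert lp == pytest.approx(-1.44, abs=1e-12)
        assert fr.predict_probability(m, row)[0] == pytest.approx(0.1916, abs=5e-4)

    def test_history_of_falls_odds_ratio_matches_printed_table(self):
        m = self._printed_model()
        i = m.names.index("history_of_falls")
        assert round(float(m.odds_ratios[i]), 2) == 2.05

    def test_missing_column_named_in_error(self):
        m = self._printed_model()
        row = pd.DataFrame({"age": [70.0]})
        with pytest.raises(KeyError, match="female_sex"):
            fr.predict_probability(m, row)
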