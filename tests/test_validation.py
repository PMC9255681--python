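"""Metric oracles, calibration properties, and nested cross-validation."""

import numpy as np
import pandas as pd
import pytest

import fallrisk as fr
from fallrisk.model import BolassoConfig
from fallrisk.validation import ValidationError, summarize_folds
from conftest import toy_logistic


def brute_force_auc(p, y, w):
    """Pairwise weighted concordance with ties counted one half."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    num = den = 0.0
    for i in pos:
        for j in neg:
            ww = w[i] * w[j]
            den += ww
            if p[i] > p[j]:
                num += ww
            elif p[i] == p[j]:
                num += 0.5 * ww
    return num / den


def brute_force_youden(p, y, w):
    best = (-np.inf, None)
    for t in np.unique(p):
        pred = p >= t
        tp = np.sum(w * (pred & (y == 1)))
        fp = np.sum(w * (pred & (y == 0)))
        fn = np.sum(w * (~pred & (y == 1)))
        tn = np.sum(w * (~pred & (y == 0)))
        J = tp / (tp + fn) + tn / (tn + fp) - 1
        if J > best[0] + 1e-12:
            best = (J, t)
    return best


class TestDiscriminationMetrics:
    def test_perfect_and_no_information_cases(self):
        y = np.tile([0.0, 1.0], 50)
        assert fr.roc_auc(y, y) == 1.0
        assert fr.brier(y, y) == 0.0
        p_const = np.full(100, 0.5)
        assert fr.roc_auc(p_const, y) == 0.5
        assert fr.brier(p_const, y) == 0.25
        assert fr.pr_auc(y, y) == 1.0

    def test_single_class_outcome_is_undefined_for_aucs(self):
        y = np.zeros(10)
        p = np.linspace(0, 1, 10)
        assert np.isnan(fr.roc_auc(p, y))
        assert np.isnan(fr.pr_auc(p, y))
        assert fr.brier(p, y) >= 0  # Brier still defined

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weighted_rocauc_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        p = rng.integers(0, 25, n) / 24.0  # discrete grid forces ties
        y = (rng.random(n) < 0.4).astype(float)
        w = rng.uniform(0.2, 1.0, n)
        assert fr.roc_auc(p, y, w) == pytest.approx(
            brute_force_auc(p, y, w), abs=1e-12
        )

    def test_brier_is_weighted_mean_squared_error(self):
        p = np.array([0.2, 0.9, 0.5])
        y = np.array([0.0, 1.0, 1.0])
        w = np.array([1.0, 0.5, 0.25])
        expect = (1.0 * 0.04 + 0.5 * 0.01 + 0.25 * 0.25) / 1.75
        assert fr.brier(p, y, w) == pytest.approx(expect, rel=1e-12)


class TestYouden:
    def test_separable_data_smallest_maximising_threshold(self):
        p = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        res = fr.youden_threshold(p, y)
        assert res["youden_j"] == pytest.approx(1.0)
        assert res["threshold"] == 0.8  # smallest among maximisers
        assert res["sensitivity"] == 1.0 and res["specificity"] == 1.0

    def test_constant_predictions_give_zero_j(self):
        p = np.full(20, 0.3)
        y = np.tile([0.0, 1.0], 10)
        assert fr.youden_threshold(p, y)["youden_j"] == pytest.approx(0.0)

    def test_single_class_raises(self):
        with pytest.raises(ValidationError):
            fr.youden_threshold(np.array([0.1, 0.2]), np.array([1.0, 1.0]))

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        p = rng.integers(0, 15, n) / 14.0
        y = (rng.random(n) < 0.3).astype(float)
        w = rng.uniform(0.2, 1.0, n)
        res = fr.youden_threshold(p, y, w)
        J, t = brute_force_youden(p, y, w)
        assert res["youden_j"] == pytest.approx(J, abs=1e-10)
        assert res["threshold"] == pytest.approx(t)


class TestCalibration:
    def test_self_calibration_within_3_sigma_per_bin(self):
        rng = np.random.default_rng(0)
        n = 5000
        p = rng.beta(2, 8, n)
        y = (rng.random(n) < p).astype(float)
        curve = fr.calibration_curve(p, y, method="decile")
        assert len(curve.predicted) == 10
        for pred, obs, cnt in zip(curve.predicted, curve.observed, curve.counts):
            sigma = np.sqrt(max(pred * (1 - pred), 1e-6) / cnt)
            assert abs(obs - pred) < 3 * sigma + 1e-9

    def test_permuted_outcomes_flatten_to_prevalence(self):
        rng = np.random.default_rng(1)
        n = 5000
        p = rng.beta(2, 8, n)
        y = rng.permutation((rng.random(n) < p).astype(float))
        curve = fr.calibration_curve(p, y, method="decile")
        prev = y.mean()
        for obs, cnt in zip(curve.observed, curve.counts):
            sigma = np.sqrt(prev * (1 - prev) / cnt)
            assert abs(obs - prev) < 4 * sigma

    def test_bin_means_aggregate_to_overall_rate(self):
        rng = np.random.default_rng(2)
        p = rng.random(1000)
        y = (rng.random(1000) < 0.3).astype(float)
        w = rng.uniform(0.5, 1.0, 1000)
        curve = fr.calibration_curve(p, y, w, method="decile")
        # weighted mean of per-bin observed equals the overall weighted rate
        bins = np.clip(
            np.searchsorted(np.quantile(p, np.linspace(0, 1, 11)), p, side="right") - 1,
            0, 9,
        )
        bin_w = np.array([w[bins == b].sum() for b in range(10)])
        pooled = np.sum(curve.observed * bin_w) / bin_w.sum()
        assert pooled == pytest.approx(np.average(y, weights=w), rel=1e-9)

    def test_heavy_ties_reduce_bins_with_warning(self):
        p = np.concatenate([np.zeros(50), np.ones(50) * 0.8])
        y = np.tile([0.0, 1.0], 50)
        with pytest.warns(UserWarning, match="bins"):
            curve = fr.calibration_curve(p, y, method="decile")
        assert len(curve.predicted) < 10

    def test_loess_recovers_smooth_trend(self):
        rng = np.random.default_rng(3)
        n = 3000
        p = rng.uniform(0.01, 0.6, n)
        y = (rng.random(n) < p).astype(float)
        curve = fr.calibration_curve(p, y, method="loess")
        assert len(curve.predicted) == 100
        mid = (curve.predicted > 0.1) & (curve.predicted < 0.5)
        assert np.max(np.abs(curve.observed[mid] - curve.predicted[mid])) < 0.08

    def test_brier_prefers_true_generating_probabilities(self):
        # over repeated draws, Brier(true p) <= Brier(perturbed p) on average
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(50):
            p = rng.beta(2, 6, 400)
            y = (rng.random(400) < p).astype(float)
            noisy = np.clip(p + rng.normal(0, 0.15, 400), 0.001, 0.999)
            diffs.append(fr.brier(noisy, y) - fr.brier(p, y))
        assert np.mean(diffs) > 0


def _toy_design(n=260, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    X, y = toy_logistic(n=n, p=4, beta=[1.5, 0, 0, 0], intercept=-1.2, seed=seed)
    if separable:
        y = X["x0"].to_numpy().copy()
    idx = pd.Index([f"P{i}" for i in range(n)], name="patient_id")
    X.index = idx
    flags = pd.DataFrame({"lookback_used": False, "no_followup_consult": False}, index=idx)
    return fr.DesignMatrix(
        X=X, y=pd.Series(y, index=idx), w=pd.Series(1.0, index=idx), flags=flags
    )


FAST = BolassoConfig(n_bootstrap=5, inner_cv_folds=3, nlambda=12, seed=0)


class TestCrossValidation:
    def test_perfectly_separable_toy_data_has_unit_rocauc(self):
        dm = _toy_design(separable=True)
        res = fr.crossvalidate(dm, FAST, k=4, seed=0)
        for f in res.folds:
            assert f.rocauc == 1.0

    def test_two_fold_smoke_on_tiny_data(self):
        dm = _toy_design(n=10, seed=1, separable=True)
        res = fr.crossvalidate(dm, FAST, k=2, seed=1)
        assert len(res.folds) == 2

    def test_summary_invariant_to_fold_order(self):
        dm = _toy_design(seed=2)
        res = fr.crossvalidate(dm, FAST, k=4, seed=2)
        again = summarize_folds(list(reversed(res.folds)))
        pd.testing.assert_frame_equal(res.summary.table, again.table)
        med = res.summary.table["median"]
        assert (res.summary.table["q25"] <= med).all()
        assert (med <= res.summary.table["q75"]).all()

    def test_zero_event_fold_raises_with_guidance(self):
        dm = _toy_design(n=40, seed=3)
        dm.y[:] = 0
        dm.y.iloc[:2] = 1
        with pytest.raises(ValidationError, match="strat"):
            fr.crossvalidate(dm, FAST, k=8, seed=3, stratified=False)

    def test_oof_predictions_cover_every_patient(self):
        dm = _toy_design(seed=4)
        res = fr.crossvalidate(dm, FAST, k=4, seed=4)
        assert res.oof_pred.notna().all()
        assert ((res.oof_pred > 0) & (res.oof_pred < 1)).all()


class TestSensitivityVariants:
    def test_empty_exclusion_reproduces_base_run(self):
        dm = _toy_design(seed=5)  # all flags False
        base = fr.crossvalidate(dm, FAST, k=4, seed=5)
        var, excluded = fr.sensitivity_variant(dm, "exclude_lookback", FAST, k=4, seed=5)
        assert excluded == 0
        pd.testing.assert_frame_equal(base.summary.table, var.summary.table)

    def test_exclusion_counts_reported(self):
        dm = _toy_design(seed=6)
        dm.flags.loc[dm.flags.index[:30], "no_followup_consult"] = True
        _, excluded = fr.sensitivity_variant(dm, "exclude_no_consult", FAST, k=4, seed=6)
        assert excluded == 30

    def test_unknown_variant_rejected(self):
        dm = _toy_design(seed=7)
        with pytest.raises(ValidationError, match="variant"):
            fr.sensitivity_variant(dm, "exclude_everyone", FAST)
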