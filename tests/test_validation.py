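"""Discrimination, calibration, optimism correction and the calibration belt."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from thermorp.validation import (
    ConfusionCounts,
    ValidationError,
    bootstrap_validate,
    brier_score,
    calibration_belt,
    calibration_intercept_slope,
    confusion_metrics,
    optimal_cutoff,
    roc_and_auc,
)


def auc_pair_counting(scores, labels):
    """Independent oracle: exhaustive concordant-pair fraction, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = wins = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1
        wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        r = roc_and_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=0)
        assert r.auc == 1.0

    def test_constant_scores_give_half(self):
        r = roc_and_auc([0.5] * 8, [1, 1, 1, 0, 0, 0, 0, 1], n_boot=0)
        assert r.auc == 0.5

    def test_toy_set_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.random(12), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, 12)
        labels[:2] = [0, 1]  # both classes present
        r = roc_and_auc(scores, labels, n_boot=0)
        assert r.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = roc_and_auc(scores, labels, n_boot=0).auc
        b = roc_and_auc(np.exp(3 * scores), labels, n_boot=0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(0.7, 0.15, 30), rng.normal(0.4, 0.15, 50)]
        labels = np.r_[np.ones(30), np.zeros(50)]
        r1 = roc_and_auc(scores, labels, n_boot=500, seed=7)
        r2 = roc_and_auc(scores, labels, n_boot=500, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both"):
            roc_and_auc([0.2, 0.4], [1, 1], n_boot=0)


class TestOptimalCutoff:
    @staticmethod
    def brute_force(scores, labels):
        best, best_c = -np.inf, None
        for c in np.unique(scores):
            pred = scores >= c
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            if j >= best - 1e-12:
                best, best_c = max(best, j), c
        return best_c

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(6, 30)
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert optimal_cutoff(scores, labels) == self.brute_force(scores, labels)

    def test_perfect_classifier_tie_breaks_to_highest(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert optimal_cutoff(scores, labels) == 0.8  # highest J=1 candidate

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        c = optimal_cutoff(scores, labels)
        assert optimal_cutoff(scores + 5.0, labels) == pytest.approx(c + 5.0)


class TestConfusionMetrics:
    def test_development_cohort_counts(self):
        full, pct = confusion_metrics(ConfusionCounts(tp=18, fn=4, tn=49, fp=8))
        assert pct["sensitivity"] == 82
        assert pct["specificity"] == 86
        assert pct["ppv"] == 69
        assert pct["accuracy"] == 85
        assert full["npv"] == pytest.approx(100 * 49 / 53)  # 92.45, prints as 92

    def test_all_correct_gives_100(self):
        _, pct = confusion_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert all(v == 100 for v in pct.values())

    def test_zero_denominator_is_undefined_not_zero(self):
        full, pct = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert full["sensitivity"] is None and pct["sensitivity"] is None
        assert full["specificity"] is not None

    def test_agrees_with_recount_from_predictions(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        yp = rng.integers(0, 2, 50)
        c = ConfusionCounts.from_predictions(y, yp)
        assert c.tp + c.fn == y.sum()
        assert c.tn + c.fp == (1 - y).sum()
        full, _ = confusion_metrics(c)
        assert full["accuracy"] == pytest.approx(100 * (y == yp).mean())

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)

    def test_counts_load_from_csv(self, tmp_path):
        path = tmp_path / "counts.csv"
        path.write_text("TP,FN,TN,FP\n18,4,49,8\n")
        c = ConfusionCounts.from_csv(path)
        assert (c.tp, c.fn, c.tn, c.fp) == (18, 4, 49, 8)


class TestBrier:
    def test_perfect_and_uninformative(self):
        assert brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0
        assert brier_score([0.5] * 4, [1, 0, 1, 0]) == 0.25

    def test_toy_vector_hand_arithmetic(self):
        p = [0.9, 0.2, 0.6, 0.4, 0.1]
        y = [1, 0, 1, 1, 0]
        expected = (0.1**2 + 0.2**2 + 0.4**2 + 0.6**2 + 0.1**2) / 5
        assert brier_score(p, y) == pytest.approx(expected, abs=1e-12)


class TestCalibration:
    def test_own_fit_calibrates_to_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(400, 2))
        eta = 0.3 + x @ [1.0, -0.8]
        y = (rng.random(400) < expit(eta)).astype(float)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        a, b = calibration_intercept_slope(fit.fittedvalues, y)
        assert a == pytest.approx(0.0, abs=1e-5)
        assert b == pytest.approx(1.0, abs=1e-5)

    def test_overconfident_predictions_have_slope_below_one(self):
        rng = np.random.default_rng(7)
        lp_true = rng.normal(0, 1, 2000)
        y = (rng.random(2000) < expit(lp_true)).astype(float)
        a, b = calibration_intercept_slope(2.0 * lp_true, y)
        assert b < 0.75


def _plain_logistic_fit_fn(predictors):
    def fit_fn(df):
        fit = sm.Logit(
            df["diagnosis"].to_numpy(float),
            sm.add_constant(df[predictors], has_constant="add"),
        ).fit(disp=0)

        def lp(dd):
            return (
                sm.add_constant(dd[predictors], has_constant="add") @ fit.params
            ).to_numpy()

        return lp

    return fit_fn


class TestBootstrapValidate:
    def _wellspecified(self, n, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        eta = -0.5 + 1.2 * df["x1"] - 0.7 * df["x2"]
        df["diagnosis"] = (rng.random(n) < expit(eta)).astype(int)
        return df

    def test_fixed_seed_is_bit_reproducible(self):
        df = self._wellspecified(300, 8)
        fn = _plain_logistic_fit_fn(["x1", "x2"])
        a = bootstrap_validate(df, fn, B=50, seed=42)
        b = bootstrap_validate(df, fn, B=50, seed=42)
        assert a == b

    def test_large_wellspecified_cohort_keeps_slope_near_one(self):
        df = self._wellspecified(2000, 9)
        res = bootstrap_validate(df, _plain_logistic_fit_fn(["x1", "x2"]),
                                 B=100, seed=0)
        assert res.apparent["calibration_slope"] == pytest.approx(1.0, abs=1e-5)
        assert res.corrected["calibration_slope"] == pytest.approx(1.0, abs=0.05)

    def test_overfit_small_sample_correction_shrinks_slope(self):
        """Corrected slope falls below the apparent slope on noisy small fits."""
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(40, 5)),
                              columns=[f"x{i}" for i in range(5)])
            eta = 0.8 * df["x0"]
            df["diagnosis"] = (rng.random(40) < expit(eta)).astype(int)
            if df["diagnosis"].nunique() < 2:
                continue
            try:
                res = bootstrap_validate(
                    df, _plain_logistic_fit_fn([f"x{i}" for i in range(5)]),
                    B=40, seed=seed,
                )
            except ValidationError:
                continue  # this replicate separates systematically
            wins += (res.corrected["calibration_slope"]
                     <= res.apparent["calibration_slope"])
        assert wins >= 0.8 * 50 * 0.7  # allow for skipped separating replicates


class TestCalibrationBelt:
    def _calibrated(self, n, seed, distort=None):
        rng = np.random.default_rng(seed)
        p = expit(rng.normal(-0.3, 1.2, n))
        y = (rng.random(n) < p).astype(float)
        if distort is not None:
            p = distort(p)
        return p, y

    def test_identity_inside_belt_on_calibrated_data(self):
        p, y = self._calibrated(2000, 10)
        belt = calibration_belt(p, y, n_grid=25)
        cover = belt.covers_identity(0.95)
        assert cover.mean() >= 0.9
        assert belt.p_value > 0.05

    def test_squared_probabilities_detected_as_miscalibrated(self):
        p, y = self._calibrated(5000, 11, distort=lambda q: q**2)
        belt = calibration_belt(p, y, compute_bands=False)
        assert belt.p_value < 0.05

    def test_belt_width_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 500, 5000):
            p, y = self._calibrated(n, 12)
            belt = calibration_belt(p, y, confidence_levels=(0.95,), n_grid=12)
            lo, hi = belt.bands[0.95]
            widths.append(float(np.mean(hi - lo)))
        assert widths[0] > widths[1] > widths[2]

    def test_bands_nested_and_contain_fit(self):
        p, y = self._calibrated(800, 13)
        belt = calibration_belt(p, y, n_grid=15)
        lo80, hi80 = belt.bands[0.80]
        lo95, hi95 = belt.bands[0.95]
        assert np.all(lo95 <= lo80 + 1e-9) and np.all(hi80 <= hi95 + 1e-9)
        assert np.all(lo95 - 1e-6 <= belt.fitted_prob)
        assert np.all(belt.fitted_prob <= hi95 + 1e-6)

    def test_degenerate_probabilities_rejected(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        with pytest.raises(ValidationError, match="degenerate"):
            calibration_belt(np.full(60, 0.4), y)

    def test_small_samples_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValidationError, match="40"):
            calibration_belt(rng.random(20), rng.integers(0, 2, 20))
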