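"""Published model constants, development procedure, and nomogram construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.base import clone

from thermorp.model import (
    BackwardEliminationLogit,
    ModelError,
    PredictionModel,
    SeparationError,
    build_nomogram,
    correlation_screen,
    fit_logistic,
    predict_probability,
    published_model,
)


class TestPublishedModel:
    def test_coefficients_and_cutoff(self):
        m = published_model()
        assert m.intercept == 2.4
        assert dict(m.coefficients) == {"time_to_t_end": 0.11, "t_base": -0.30}
        assert m.cutoff == 0.46
        assert m.provenance == "published"

    def test_worked_example_probability(self):
        # logistic(2.4 + 0.11*60 - 0.30*26.5) = logistic(1.05)
        p = predict_probability(published_model(), 60.0, 26.5)
        assert p == pytest.approx(expit(1.05), abs=1e-12)
        assert p == pytest.approx(0.741, abs=0.001)
        assert published_model().classify(p) == "positive"

    def test_boundary_probability_counts_positive(self):
        m = published_model()
        assert m.classify(0.46) == "positive"
        assert m.classify(0.0) == "negative"

    def test_zero_coefficients_give_half(self):
        m = PredictionModel(intercept=0.0, coefficients={"time_to_t_end": 0.0,
                                                         "t_base": 0.0})
        assert predict_probability(m, 17.0, 29.0) == pytest.approx(0.5)

    def test_monotone_in_each_predictor(self):
        m = published_model()
        p = [predict_probability(m, t, 30.0) for t in np.linspace(0, 60, 20)]
        assert np.all(np.diff(p) > 0)
        p = [predict_probability(m, 20.0, b) for b in np.linspace(24, 36, 20)]
        assert np.all(np.diff(p) < 0)

    def test_minutes_are_the_required_time_unit(self):
        """The worked example is positive only with time in minutes, not hours."""
        m = published_model()
        assert m.classify(predict_probability(m, 60.0, 26.5)) == "positive"
        assert m.classify(predict_probability(m, 1.0, 26.5)) == "negative"

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ModelError, match="cutoff"):
            PredictionModel(intercept=0.0, coefficients={"x": 1.0}, cutoff=1.5)


class TestCorrelationScreen:
    def test_perfectly_collinear_pair_keeps_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        assert correlation_screen(df) == ["x"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((1000, 4)),
                          columns=["a", "b", "c", "d"])
        assert correlation_screen(df) == ["a", "b", "c", "d"]

    def test_toy_table_against_hand_computed_r(self):
        # 5-point table: r(u, v) computed by the textbook formula
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 4.1, 5.9, 8.2, 9.8])
        w = np.array([3.0, -1.0, 4.0, 0.0, 2.0])
        r_uv = np.sum((u - u.mean()) * (v - v.mean())) / np.sqrt(
            np.sum((u - u.mean()) ** 2) * np.sum((v - v.mean()) ** 2)
        )
        assert abs(r_uv - np.corrcoef(u, v)[0, 1]) < 1e-12
        assert r_uv > 0.75  # u and v are nearly collinear; w is not
        df = pd.DataFrame({"u": u, "v": v, "w": w})
        assert correlation_screen(df) == ["u", "w"]

    def test_priority_decides_which_member_is_kept(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        df = pd.DataFrame({"low": x + rng.normal(0, 0.01, 50), "high": x})
        assert correlation_screen(df, priority=["high", "low"]) == ["high"]

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ModelError, match="constant"):
            correlation_screen(df)


def simulate_from_published(n, seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "time_to_t_end": rng.uniform(0, 60, n),
            "t_base": rng.normal(30, 2, n),
        }
    )
    p = published_model().predict_probability(df)
    df["diagnosis"] = (rng.random(n) < p).astype(int)
    return df


class TestBackwardElimination:
    def test_noise_predictor_eliminated_in_majority_of_seeds(self):
        wins = 0
        for seed in range(50):
            df = simulate_from_published(400, seed)
            rng = np.random.default_rng(seed + 10_000)
            df["noise"] = rng.standard_normal(len(df))
            est = BackwardEliminationLogit(cutoff=0.5)
            est.fit(df[["time_to_t_end", "t_base", "noise"]], df["diagnosis"])
            wins += "noise" not in est.selected_features_
        assert wins > 25

    def test_null_outcome_reduces_to_intercept_only(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 300)
        est = BackwardEliminationLogit(cutoff=0.5).fit(df, y)
        assert est.selected_features_ == []
        assert est.predict_proba(df)[:, 1] == pytest.approx(y.mean(), abs=1e-6)

    def test_perfect_separation_flagged_with_predictor_name(self):
        df = pd.DataFrame({"sep": np.r_[np.zeros(20), np.ones(20)],
                           "other": np.random.default_rng(0).normal(size=40)})
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            BackwardEliminationLogit(screen=False, cutoff=0.5).fit(df, y)

    def test_consistency_as_n_grows(self):
        """Coefficient error shrinks as the simulated sample grows."""
        errors = []
        for n in (250, 1000, 4000):
            df = simulate_from_published(n, seed=123)
            est = BackwardEliminationLogit(screen=False, cutoff=0.5)
            est.fit(df[["time_to_t_end", "t_base"]], df["diagnosis"])
            coefs = dict(zip(est.selected_features_, est.coef_))
            errors.append(abs(coefs["time_to_t_end"] - 0.11)
                          + abs(coefs["t_base"] + 0.30))
        assert errors[2] < errors[0]

    def test_summary_reports_wald_columns(self):
        df = simulate_from_published(800, seed=5)
        est = BackwardEliminationLogit(screen=False, cutoff=0.5)
        est.fit(df[["time_to_t_end", "t_base"]], df["diagnosis"])
        summ = est.summary_frame()
        assert list(summ.columns) == ["estimate", "std_error", "wald_z",
                                      "wald_chi2", "p_value"]
        assert np.allclose(summ["wald_chi2"], summ["wald_z"] ** 2)

    def test_sklearn_clone_and_get_params_roundtrip(self):
        est = BackwardEliminationLogit(p_stay=0.1, cutoff=0.4)
        cloned = clone(est)
        assert cloned.get_params()["p_stay"] == 0.1
        assert cloned.get_params()["cutoff"] == 0.4

    def test_fit_logistic_wrapper_on_simulated_subjects(self):
        df = simulate_from_published(600, seed=77)
        df["age"] = np.random.default_rng(77).normal(57, 11, len(df))
        model, summary = fit_logistic(df)
        assert model.provenance == "refit"
        assert 0 < model.cutoff < 1
        assert set(summary.index) == {"const", *model.predictors}


class TestNomogram:
    RANGES = {"time_to_t_end": (0.0, 60.0), "t_base": (24.0, 36.0)}

    def test_reference_value_scores_zero_points(self):
        nomo = build_nomogram(published_model(), self.RANGES)
        assert nomo.points("time_to_t_end", 0.0) == 0.0
        assert nomo.points("t_base", 36.0) == 0.0  # negative slope: top of range

    def test_points_nonnegative_and_widest_axis_spans_100(self):
        nomo = build_nomogram(published_model(), self.RANGES)
        maxima = []
        for name, (lo, hi) in self.RANGES.items():
            pts = [nomo.points(name, v) for v in np.linspace(lo, hi, 50)]
            assert min(pts) >= 0
            maxima.append(max(pts))
        assert max(maxima) == pytest.approx(100.0)

    def test_lookup_agrees_with_direct_probability_on_grid(self):
        m = published_model()
        nomo = build_nomogram(m, self.RANGES)
        for t in np.linspace(0, 60, 10):
            for b in np.linspace(24, 36, 10):
                direct = predict_probability(m, t, b)
                via = nomo.lookup({"time_to_t_end": t, "t_base": b})
                assert abs(via - direct) < 0.01

    def test_probability_monotone_in_total_points(self):
        nomo = build_nomogram(published_model(), self.RANGES)
        probs = [nomo.probability(tp) for tp in np.linspace(0, 200, 30)]
        assert np.all(np.diff(probs) > 0)

    def test_worked_example_above_cutoff(self):
        nomo = build_nomogram(published_model(), self.RANGES)
        p = nomo.lookup({"time_to_t_end": 60.0, "t_base": 26.5})
        assert p >= nomo.cutoff

    def test_zero_coefficient_predictor_excluded_with_warning(self):
        m = PredictionModel(intercept=0.0,
                            coefficients={"a": 1.0, "b": 0.0})
        with pytest.warns(UserWarning, match="zero coefficient"):
            nomo = build_nomogram(m, {"a": (0, 1), "b": (0, 1)})
        assert list(nomo.coefficients) == ["a"]

    def test_render_writes_figure(self, tmp_path):
        from thermorp.model import render_nomogram

        nomo = build_nomogram(published_model(), self.RANGES)
        out = tmp_path / "nomogram.png"
        render_nomogram(nomo, str(out))
        assert out.stat().st_size > 0
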