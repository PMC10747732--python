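import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from runload.evaluate import (SplitResult, calibration_stats, correlation,
                              enet_importance, gbt_importance, nrmse,
                              repeated_split_eval, select_best, summarize)
from runload.models import ElasticNetSpec, GbtSpec


class _OracleSpec:
    """Duck-typed 'model' that reads the truth off the first column."""

    def fit(self, X, y, seed):
        class _M:
            def predict(self_inner, Xte):
                return np.asarray(Xte)[:, 0]
        return _M()


class _MeanBaseline:
    def fit(self, X, y, seed):
        mean = float(np.mean(y))
        class _M:
            def predict(self_inner, Xte):
                return np.full(len(Xte), mean)
        return _M()


class TestMetrics:
    def test_nrmse_zero_for_perfect_prediction(self):
        assert nrmse([1.0, 2.0], [1.0, 2.0], 1.5) == 0.0

    def test_nrmse_constant_offset_closed_form(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert nrmse(obs + 0.5, obs, 2.0) == pytest.approx(0.5 / 2.0)

    def test_nrmse_hand_arithmetic(self):
        val = nrmse([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], 2.0)
        assert val == pytest.approx(np.sqrt(2.0 / 3.0) / 2.0)

    def test_nrmse_rejects_bad_mean(self):
        with pytest.raises(ValueError):
            nrmse([1.0], [1.0], 0.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 50))
    def test_nrmse_scale_invariant(self, c, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(1.0, 5.0, size=20)
        pred = obs + rng.normal(size=20)
        base = nrmse(pred, obs, obs.mean())
        scaled = nrmse(c * pred, c * obs, c * obs.mean())
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_correlation_affine_invariance(self):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        assert correlation(2 * obs + 1, obs) == pytest.approx(1.0)
        assert correlation(-obs, obs) == pytest.approx(-1.0)

    def test_correlation_undefined_for_constant_vector(self):
        assert correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) is None

    def test_correlation_needs_two_points(self):
        with pytest.raises(ValueError):
            correlation([1.0], [1.0])


class TestRepeatedSplits:
    def test_zero_splits_gives_empty_list(self, tiny_data):
        dm = tiny_data.design_matrices[6]
        out = repeated_split_eval(dm.X, dm.targets["patella"],
                                  ElasticNetSpec(alpha=0.0, lam=1.0),
                                  n_splits=0)
        assert out == []

    def test_perfect_predictor_scores_perfectly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.uniform(1, 5, 60),
                          "b": rng.normal(size=60)})
        y = X["a"].to_numpy()
        results = repeated_split_eval(X, y, _OracleSpec(), n_splits=20,
                                      seed=1)
        assert all(r.correlation == pytest.approx(1.0) for r in results)
        assert all(r.nrmse == pytest.approx(0.0, abs=1e-12) for r in results)

    def test_mean_baseline_nrmse_matches_dispersion(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=300)})
        y = rng.uniform(2.0, 6.0, size=300)
        results = repeated_split_eval(X, y, _MeanBaseline(), n_splits=200,
                                      seed=2)
        assert all(r.constant_predictor for r in results)
        assert all(r.correlation is None for r in results)
        summary = summarize(results)
        assert summary.n_undefined == 200
        expected = np.std(y) / np.mean(y)
        assert summary.mean_nrmse == pytest.approx(expected, rel=0.1)

    def test_train_frac_validated(self, tiny_data):
        dm = tiny_data.design_matrices[6]
        with pytest.raises(ValueError):
            repeated_split_eval(dm.X, dm.targets["patella"],
                                ElasticNetSpec(), train_frac=1.5)

    def test_undefined_correlations_excluded_from_mean(self):
        results = [
            SplitResult(0, 0.8, 0.1, False),
            SplitResult(1, None, 0.3, True),
            SplitResult(2, 0.6, 0.2, False),
        ]
        s = summarize(results)
        assert s.mean_correlation == pytest.approx(0.7)
        assert s.n_undefined == 1
        assert s.mean_nrmse == pytest.approx(0.2)

    def test_split_average_stable_in_split_count(self, study_data):
        # halving-then-some the number of splits moves the average by less
        # than 3 Monte-Carlo standard errors
        dm = study_data.design_matrices[6]
        y = dm.targets["patella"].to_numpy()
        spec = ElasticNetSpec(alpha=0.0)
        many = repeated_split_eval(dm.X, y, spec, n_splits=2500, seed=5)
        few = repeated_split_eval(dm.X, y, spec, n_splits=250, seed=5)
        corr_many = np.array([r.correlation for r in many], dtype=float)
        corr_few = np.array([r.correlation for r in few], dtype=float)
        se = corr_many.std(ddof=1) / np.sqrt(corr_few.size)
        assert abs(corr_many.mean() - corr_few.mean()) < 3 * se


class TestSelection:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_single_cell_grid(self):
        t = self._table([{"target": "patella", "config_id": 6,
                          "family": "elastic_net", "model": "enet a=1",
                          "mean_nrmse": 0.1, "mean_correlation": 0.9}])
        best = select_best(t)
        assert best["patella"]["model"] == "enet a=1"

    def test_dominant_cell_selected(self):
        rows = [{"target": "achilles", "config_id": c,
                 "family": "gbt", "model": f"xgb d=3 eta=0.1",
                 "mean_nrmse": 0.2 + 0.01 * c, "mean_correlation": 0.5}
                for c in range(1, 8)]
        rows[4]["mean_nrmse"] = 0.05
        best = select_best(self._table(rows))
        assert best["achilles"]["config_id"] == 5

    def test_ties_break_toward_fewer_sensors(self):
        rows = [
            {"target": "patella", "config_id": 5, "family": "elastic_net",
             "model": "enet a=1", "mean_nrmse": 0.1},
            {"target": "patella", "config_id": 6, "family": "elastic_net",
             "model": "enet a=1", "mean_nrmse": 0.1},
        ]
        best = select_best(self._table(rows))
        assert best["patella"]["config_id"] == 6


class TestCalibration:
    def test_perfect_predictions_give_identity_line(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(1, 10, size=400)
        cal = calibration_stats(pred, pred, subsample=250, seed=1)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.slope == pytest.approx(1.0, rel=1e-9)
        assert cal.indices.size == 250

    def test_half_scale_predictions_double_slope(self):
        rng = np.random.default_rng(4)
        obs = rng.uniform(1, 10, size=300)
        cal = calibration_stats(obs / 2.0, obs, subsample=250, seed=1)
        assert cal.slope == pytest.approx(2.0, rel=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_four_point_normal_equations(self):
        pred = np.array([0.0, 1.0, 2.0, 3.0] * 100)
        obs = np.array([1.0, 3.0, 2.0, 5.0] * 100)
        cal = calibration_stats(pred, obs, subsample=400, seed=0)
        A = np.column_stack([np.ones(400), pred[cal.indices]])
        beta = np.linalg.lstsq(A, obs[cal.indices], rcond=None)[0]
        assert cal.intercept == pytest.approx(beta[0])
        assert cal.slope == pytest.approx(beta[1])

    def test_degenerate_variance_flagged(self):
        cal = calibration_stats(np.ones(300), np.arange(300.0),
                                subsample=250, seed=0)
        assert cal.degenerate
        assert cal.slope is None


class TestImportance:
    def _enet_results(self, C):
        return [SplitResult(i, 0.9, 0.1, False, enet_coef_std=row)
                for i, row in enumerate(C)]

    def test_always_zero_predictor_has_zero_inclusion_worst_rank(self):
        C = np.array([[1.0, 0.0, 0.5], [0.8, 0.0, 0.2], [1.2, 0.0, 0.9]])
        rep = enet_importance(self._enet_results(C), ["a", "b", "c"])
        assert rep.inclusion_frequency[1] == 0.0
        assert rep.effect_size_rank[1] == 3.0
        assert "b" in rep.below_10pct
        assert set(rep.at_least_90pct) == {"a", "c"}

    def test_single_signal_recovery_rank_one(self, study_data):
        dm = study_data.design_matrices[6]
        driver = dm.X["left_ankle_amag_dc"].to_numpy()
        y = 3.0 * driver
        results = repeated_split_eval(dm.X, y, ElasticNetSpec(alpha=1.0),
                                      n_splits=8, seed=9,
                                      collect_importance=True)
        rep = enet_importance(results, dm.column_names)
        idx = dm.column_names.index("left_ankle_amag_dc")
        assert rep.inclusion_frequency[idx] == 1.0
        assert rep.effect_size_rank[idx] == 1.0

    def test_schema_mismatch_rejected(self):
        C = np.ones((3, 2))
        with pytest.raises(ValueError):
            enet_importance(self._enet_results(C), ["a", "b", "c"])

    def test_gbt_single_informative_feature_tops_gain_ranks(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(150, 6)), columns=list("abcdef"))
        y = 2.0 * X["a"].to_numpy() + 0.05 * rng.normal(size=150)
        results = repeated_split_eval(
            X, y, GbtSpec(depth=2, learning_rate=0.3, n_trees=15),
            n_splits=4, seed=10, collect_importance=True)
        rep = gbt_importance(results, list(X.columns))
        assert rep.gain_rank[0] == 1.0
        assert np.all(rep.mean_gain >= 0.0)
        assert np.all(np.isfinite(rep.mean_gain))
        assert rep.mean_gain[0] == rep.mean_gain.max()
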