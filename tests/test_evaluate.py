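import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirchem.evaluate import (EvalDistribution, boxplot_stats, metrics,
                              repeated_evaluation, split_data, summarize)


class TestSplitData:
    def test_paper_scale_sizes(self):
        plan = split_data(150, seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == \
            (90, 15, 45)

    def test_exact_fractions_n10(self):
        plan = split_data(10, (0.6, 0.1, 0.3), seed=1)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == \
            (6, 1, 3)

    def test_same_seed_identical(self):
        a, b = split_data(37, seed=5), split_data(37, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_partition_covers_everything(self):
        plan = split_data(23, seed=2)
        all_idx = np.concatenate([plan.train, plan.validation, plan.test])
        assert sorted(all_idx.tolist()) == list(range(23))

    def test_empty_part_rejected(self):
        with pytest.raises(ValueError, match="empty|small"):
            split_data(3, (0.6, 0.1, 0.3), seed=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split_data(20, (0.5, 0.1, 0.3), seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(y, y)
        assert (m.r, m.r2, m.mse, m.rmse, m.mae) == (1.0, 1.0, 0.0, 0.0, 0.0)

    def test_shifted_identity(self):
        m = metrics(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        assert m.r == pytest.approx(1.0)
        assert m.mse == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)

    def test_error_arithmetic(self):
        m = metrics(np.array([0.0, 0, 2, 2]), np.array([1.0, 1, 1, 1.0001]))
        assert m.mse == pytest.approx(1.0, abs=1e-3)
        assert m.mae == pytest.approx(1.0, abs=1e-3)

    def test_constant_y_true_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            metrics(np.array([2.0, 2, 2]), np.array([1.0, 2, 3]))

    def test_constant_y_pred_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            metrics(np.array([0.0, 0, 2, 2]), np.zeros(4))

    @given(arrays(float, 12, elements=st.floats(-50, 50)),
           arrays(float, 12, elements=st.floats(-50, 50)))
    @settings(max_examples=40, deadline=None)
    def test_algebraic_identities(self, yt, yp):
        if np.std(yt) == 0 or np.std(yp) == 0:
            return
        m = metrics(yt, yp)
        assert m.rmse ** 2 == pytest.approx(m.mse, rel=1e-12)
        assert m.mae <= m.rmse + 1e-12
        assert -1.0 - 1e-12 <= m.r <= 1.0 + 1e-12
        assert m.r2 == pytest.approx(m.r ** 2, rel=1e-12)

    def test_r_invariant_to_positive_affine_pred(self):
        rng = np.random.default_rng(0)
        yt = rng.standard_normal(30)
        yp = yt + 0.3 * rng.standard_normal(30)
        assert metrics(yt, 2.5 * yp + 7).r == pytest.approx(metrics(yt, yp).r)


def _mean_pipeline(X_tr, y_tr, X_val, y_val, seed):
    mu = float(np.mean(y_tr))
    rng = np.random.default_rng(seed)

    def predict(X):
        # jitter keeps predictions non-constant so r is defined
        return mu + 1e-9 * rng.standard_normal(len(X))

    return predict


class TestRepeatedEvaluation:
    def test_mean_pipeline_runs(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        d = repeated_evaluation(X, y, _mean_pipeline, n_iter=3, base_seed=10)
        assert len(d.records) == 3
        assert all(abs(m.r) < 0.9 for m in d.records)

    def test_same_base_seed_identical(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 2))
        y = X @ np.array([1.0, -1.0])

        def pipe(X_tr, y_tr, X_val, y_val, seed):
            coef, *_ = np.linalg.lstsq(
                np.column_stack([X_tr, np.ones(len(y_tr))]), y_tr, rcond=None)
            return lambda Xq: Xq @ coef[:-1] + coef[-1]

        d1 = repeated_evaluation(X, y, pipe, n_iter=5, base_seed=3)
        d2 = repeated_evaluation(X, y, pipe, n_iter=5, base_seed=3)
        assert [m.mse for m in d1.records] == [m.mse for m in d2.records]

    def test_failed_iterations_excluded_and_counted(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)

        calls = {"n": 0}

        def flaky(X_tr, y_tr, X_val, y_val, seed):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return _mean_pipeline(X_tr, y_tr, X_val, y_val, seed)

        d = repeated_evaluation(X, y, flaky, n_iter=4, base_seed=0)
        assert d.n_failed == 1
        assert len(d.records) == 3

    def test_paper_scale_supported(self):
        # contract: n_iter=500 accepted (cheap pipeline keeps this fast)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        d = repeated_evaluation(X, y, _mean_pipeline, n_iter=500, base_seed=0)
        assert len(d.records) + d.n_failed == 500


class TestSummarize:
    def _dist(self, mses):
        records = []
        for mse in mses:
            yt = np.array([0.0, 1.0, 2.0])
            yp = yt + np.sqrt(mse)
            records.append(metrics(yt, yp))
        return EvalDistribution(records, list(range(len(mses))), "toy")

    def test_identical_records(self):
        s = summarize(self._dist([0.25, 0.25, 0.25]))
        assert s.loc["sd", "mse"] == pytest.approx(0.0)
        assert s.loc["best", "mse"] == pytest.approx(0.25)

    def test_mean_and_best(self):
        s = summarize(self._dist([0.1, 0.3]))
        assert s.loc["mean", "mse"] == pytest.approx(0.2)
        assert s.loc["best", "mse"] == pytest.approx(0.1)

    def test_quartiles_ordered(self):
        s = summarize(self._dist([0.1, 0.2, 0.4, 0.8, 1.0]))
        for col in s.columns:
            assert s.loc["q1", col] <= s.loc["median", col] <= s.loc["q3", col]

    def test_best_mse_not_above_mean(self):
        s = summarize(self._dist([0.1, 0.5, 0.9]))
        assert s.loc["best", "mse"] <= s.loc["mean", "mse"]

    def test_best_seed_recorded(self):
        d = self._dist([0.4, 0.1, 0.6])
        assert summarize(d).attrs["best_seed"] == 1


def test_boxplot_stats_keys():
    yt = np.linspace(0, 5, 20)
    rng = np.random.default_rng(0)
    records = [
        metrics(yt, yt + rng.standard_normal(20) * 0.3) for _ in range(10)
    ]
    d = EvalDistribution(records, list(range(10)), "toy")
    stats = boxplot_stats(d)
    assert set(stats) == {"mse", "rmse", "mae", "r", "r2"}
    for v in stats.values():
        assert v["q1"] <= v["median"] <= v["q3"]
        assert v["whisker_low"] <= v["q1"]
        assert v["whisker_high"] >= v["q3"]
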