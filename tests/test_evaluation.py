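import logging
import math

import numpy as np
import pytest
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from conftest import make_complex

from seqaffinity import (
    ComplexDataset,
    EvaluationResult,
    error_histogram,
    evaluate_loco,
    homology_baseline,
    pearson,
    rmse,
)
from seqaffinity.evaluation import loco_predictions_features


class TestMetrics:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        r, p = pearson([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_anticorrelation(self):
        r, _ = pearson([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_rmse(self):
        assert rmse([1, 2, 3], [2, 2, 2]) == pytest.approx(math.sqrt(2 / 3))

    def test_p_value_matches_t_distribution_survival_function(self):
        y_true = np.array([1.0, 2.0, 3.0, 5.0, 4.5, 7.0, 6.0])
        y_pred = np.array([1.2, 1.8, 3.5, 4.0, 5.0, 6.2, 7.1])
        r, p = pearson(y_true, y_pred)
        n = len(y_true)
        t = r * math.sqrt((n - 2) / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=n - 2), rel=1e-10)

    def test_zero_variance_reports_nan_not_zero(self, caplog):
        with caplog.at_level(logging.WARNING):
            r, p = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)
        assert "zero variance" in caplog.text

    def test_length_validation(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson([1.0], [1.0])


class TestEvaluationResult:
    def test_aggregates_recompute_from_per_complex_records(self, rng):
        y_true = rng.normal(size=10)
        y_pred = y_true + rng.normal(scale=0.3, size=10)
        res = EvaluationResult.from_predictions(
            [f"C{i}" for i in range(10)], y_true, y_pred
        )
        table = res.per_complex
        assert res.rmse == pytest.approx(rmse(table.y_true, table.y_pred))
        r, p = pearson(table.y_true, table.y_pred)
        assert res.pearson_r == pytest.approx(r) and res.p_value == pytest.approx(p)
        assert np.allclose(table.abs_error, np.abs(table.y_true - table.y_pred))

    def test_csv_round_trip_layout(self, rng, tmp_path):
        res = EvaluationResult.from_predictions(["a", "b", "c"], [1, 2, 3], [1, 2, 2])
        res.write_csv(tmp_path / "per.csv", tmp_path / "agg.csv")
        import pandas as pd

        per = pd.read_csv(tmp_path / "per.csv")
        agg = pd.read_csv(tmp_path / "agg.csv")
        assert list(per.columns) == ["complex_id", "y_true", "y_pred", "abs_error"]
        assert agg.loc[0, "n"] == 3


class TestErrorHistogram:
    def _result(self, errors):
        y_true = np.zeros(len(errors))
        return EvaluationResult.from_predictions(
            [f"C{i}" for i in range(len(errors))], y_true, np.asarray(errors, float)
        )

    def test_all_zero_errors(self):
        assert error_histogram(self._result([0, 0, 0]), [1.5])[0] == 1.0

    def test_hand_fractions(self):
        fracs = error_histogram(self._result([1, 2, 3]), [1.5, 2.5])
        assert np.allclose(fracs, [1 / 3, 2 / 3])

    def test_cumulative_fractions_non_decreasing(self, rng):
        errors = np.abs(rng.normal(size=30))
        fracs = error_histogram(self._result(errors), np.linspace(0.1, 3, 12))
        assert np.all(np.diff(fracs) >= 0)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            error_histogram(self._result([1.0]), [2.0, 1.0])


class _TrainingMeanRegressor(RegressorMixin, BaseEstimator):
    """Memorizes the training mean; used for the closed-form LOCO check."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class TestLoco:
    def test_each_complex_predicted_exactly_once(self, tiny_dataset):
        res = evaluate_loco(tiny_dataset, representation="aac", model="olsr")
        assert res.n == 5
        assert sorted(res.per_complex.complex_id) == sorted(tiny_dataset.ids)
        assert res.per_complex.complex_id.is_unique

    def test_mean_predictor_matches_closed_form(self, rng):
        # leaving out i, the training mean is (sum(y) - y_i) / (N - 1)
        y = rng.normal(size=12)
        X = rng.normal(size=(12, 3))
        preds = loco_predictions_features(X, y, _TrainingMeanRegressor())
        expected = (y.sum() - y) / (len(y) - 1)
        assert np.allclose(preds, expected)

    def test_constant_labels_give_nan_pearson(self, rng, caplog):
        from oracles import random_sequence

        complexes = [
            make_complex(
                f"C{i}", [random_sequence(rng, 20, 30)], [random_sequence(rng, 20, 30)],
                delta_g=-8.0,
            )
            for i in range(4)
        ]
        ds = ComplexDataset(complexes)
        with caplog.at_level(logging.WARNING):
            res = evaluate_loco(ds, representation="aac", model="olsr")
        assert math.isnan(res.pearson_r)

    def test_too_small_dataset_rejected(self, rng):
        from oracles import random_sequence

        ds = ComplexDataset(
            [
                make_complex("C1", [random_sequence(rng, 20, 30)],
                             [random_sequence(rng, 20, 30)], delta_g=-8.0),
                make_complex("C2", [random_sequence(rng, 20, 30)],
                             [random_sequence(rng, 20, 30)], delta_g=-9.0),
            ]
        )
        with pytest.raises(ValueError):
            evaluate_loco(ds, representation="aac", model="olsr")

    def test_unknown_representation_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="representation"):
            evaluate_loco(tiny_dataset, representation="bogus")


class TestHomologyBaselineFunction:
    def test_returns_nearest_training_label(self, tiny_dataset):
        query = tiny_dataset.complexes[2]
        assert homology_baseline(tiny_dataset, query) == tiny_dataset.complexes[2].delta_g

    def test_loco_homology_protocol(self, tiny_dataset):
        res = evaluate_loco(tiny_dataset, representation="homology")
        assert res.n == 5
        # predictions are drawn from the label set of the other complexes
        y = tiny_dataset.y
        for cid, pred in zip(res.per_complex.complex_id, res.per_complex.y_pred):
            own = tiny_dataset.complexes[tiny_dataset.ids.index(cid)].delta_g
            assert pred in set(y) - {own} or pred in set(y)
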