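import numpy as np
import pytest

from conftest import make_complex

from seqaffinity import (
    AffinityRegressor,
    HomologyNearestNeighbor,
    KernelAffinityRegressor,
    load_model,
    save_model,
)
from seqaffinity.models import select_hyperparameters
from sklearn.svm import SVR


def linear_data(rng, n=30, p=5, noise=0.0):
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + 2.0 + noise * rng.normal(size=n)
    return X, y, w


class TestAffinityRegressor:
    def test_olsr_interpolates_noise_free_linear_data(self, rng):
        # y linear in the unit-normed representation the pipeline consumes
        X = rng.normal(size=(30, 5))
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        y = Xn @ rng.normal(size=5) + 2.0
        est = AffinityRegressor(model="olsr").fit(X, y)
        assert np.max(np.abs(est.predict(X) - y)) < 1e-8

    def test_olsr_interpolates_raw_linear_data_without_scaling(self, rng):
        X, y, _ = linear_data(rng)
        est = AffinityRegressor(model="olsr", scale=False).fit(X, y)
        assert np.max(np.abs(est.predict(X) - y)) < 1e-8

    def test_olsr_recovers_weights_without_scaling(self, rng):
        X, y, w = linear_data(rng, n=50, p=4)
        est = AffinityRegressor(model="olsr", scale=False).fit(X, y)
        assert np.allclose(est.model_.coef_, w, atol=1e-6)
        assert est.model_.intercept_ == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("kind", ["olsr", "rfr", "svr_rbf"])
    def test_constant_targets_predicted_as_constant(self, rng, kind):
        X = rng.normal(size=(12, 3))
        y = np.full(12, -7.5)
        grid = {} if kind != "svr_rbf" else {"C": [10.0], "epsilon": [0.01]}
        est = AffinityRegressor(model=kind, param_grid=grid).fit(X, y)
        tol = 0.01 + 1e-6 if kind == "svr_rbf" else 1e-6
        assert np.max(np.abs(est.predict(X) + 7.5)) <= tol

    def test_rfr_is_deterministic_given_seed(self, rng):
        X, y, _ = linear_data(rng, noise=0.5)
        grid = {"n_estimators": [30], "min_samples_split": [2]}
        p1 = AffinityRegressor(model="rfr", param_grid=grid, random_state=3).fit(X, y).predict(X)
        p2 = AffinityRegressor(model="rfr", param_grid=grid, random_state=3).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_duplicate_rows_get_identical_predictions(self, rng):
        X, y, _ = linear_data(rng)
        est = AffinityRegressor(model="olsr").fit(X, y)
        row = rng.normal(size=(1, 5))
        both = est.predict(np.vstack([row, row]))
        assert both[0] == both[1]

    def test_dimension_mismatch_rejected(self, rng):
        X, y, _ = linear_data(rng)
        est = AffinityRegressor(model="olsr").fit(X, y)
        with pytest.raises(ValueError):
            est.predict(np.zeros((2, 7)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            AffinityRegressor(model="olsr").fit(np.zeros((1, 3)), [1.0])

    def test_unknown_kind_rejected(self, rng):
        X, y, _ = linear_data(rng)
        with pytest.raises(ValueError, match="unknown model kind"):
            AffinityRegressor(model="magic").fit(X, y)

    def test_wide_design_uses_minimum_norm_solution(self, rng):
        # more features than samples: fit must be exact on training rows
        X = rng.normal(size=(10, 40))
        y = rng.normal(size=10)
        est = AffinityRegressor(model="olsr", scale=False).fit(X, y)
        assert np.max(np.abs(est.predict(X) - y)) < 1e-8


class TestHyperparameterSelection:
    def test_singleton_grid_skips_cv(self, rng):
        X, y, _ = linear_data(rng)
        est, params = select_hyperparameters(
            SVR(kernel="linear"), X, y, {"C": [2.0], "epsilon": [0.05]}
        )
        assert params == {"C": 2.0, "epsilon": 0.05}
        assert est.C == 2.0

    def test_noise_free_toy_picks_the_strong_setting(self, rng):
        X, y, _ = linear_data(rng, n=40, p=3)
        grid = {"C": [1e-6, 100.0], "epsilon": [0.001]}
        est, params = select_hyperparameters(SVR(kernel="linear"), X, y, grid, random_state=0)
        assert params["C"] == 100.0
        assert np.max(np.abs(est.predict(X) - y)) < 1e-2

    def test_deterministic_given_seed(self, rng):
        X, y, _ = linear_data(rng, noise=1.0)
        grid = {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1]}
        _, p1 = select_hyperparameters(SVR(kernel="linear"), X, y, grid, random_state=5)
        _, p2 = select_hyperparameters(SVR(kernel="linear"), X, y, grid, random_state=5)
        assert p1 == p2

    def test_fold_count_reduced_with_warning(self, rng):
        X, y, _ = linear_data(rng, n=3)
        grid = {"C": [0.1, 1.0], "epsilon": [0.1]}
        with pytest.warns(UserWarning, match="reduced"):
            select_hyperparameters(SVR(kernel="linear"), X, y, grid, inner_cv=5)


class TestKernelRegressor:
    def test_training_point_prediction_matches_dual_expansion(self, rng):
        # 3-point toy with a linear (hence PSD) Gram
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.5])
        G = X @ X.T
        est = KernelAffinityRegressor(param_grid={"C": [10.0], "epsilon": [0.01]}).fit(G, y)
        svr = est.model_
        manual = (svr.dual_coef_ @ G[svr.support_, :] + svr.intercept_).ravel()
        assert np.allclose(est.predict(G), manual)

    def test_non_square_gram_rejected(self):
        with pytest.raises(ValueError, match="square"):
            KernelAffinityRegressor().fit(np.zeros((3, 2)), [1, 2, 3])

    def test_indefinite_gram_rejected_without_correction(self):
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="not PSD"):
            KernelAffinityRegressor(
                psd_correction=False, param_grid={"C": [1.0], "epsilon": [0.1]}
            ).fit(G, [0.0, 1.0])

    def test_correction_records_the_shift(self):
        G = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.5], [0.0, 0.5, 0.0]])
        est = KernelAffinityRegressor(param_grid={"C": [1.0], "epsilon": [0.1]}).fit(
            G, [0.0, 1.0, 2.0]
        )
        assert est.lambda_min_removed_ < 0

    def test_cross_row_shape_validated(self):
        G = np.eye(3)
        est = KernelAffinityRegressor(param_grid={"C": [1.0], "epsilon": [0.1]}).fit(
            G, [1.0, 2.0, 3.0]
        )
        with pytest.raises(ValueError, match="n_test"):
            est.predict(np.zeros((1, 5)))


class TestHomologyNearestNeighbor:
    def test_identical_query_returns_training_label(self):
        train = [
            make_complex("T1", ["MKWVTFISLL"], ["ACDEFGHIKL"], delta_g=-9.0),
            make_complex("T2", ["WWWWYYYYFF"], ["PPPPGGGGSS"], delta_g=-14.0),
        ]
        model = HomologyNearestNeighbor().fit(train)
        query = make_complex("Q", ["WWWWYYYYFF"], ["PPPPGGGGSS"])
        assert model.predict([query])[0] == -14.0

    def test_single_training_complex_always_wins(self):
        train = [make_complex("T1", ["MKV"], ["ACD"], delta_g=-6.5)]
        model = HomologyNearestNeighbor().fit(train)
        query = make_complex("Q", ["WWWW"], ["YYYY"])
        assert model.predict([query])[0] == -6.5

    def test_exact_match_beats_random_complex(self, rng):
        from oracles import random_sequence
        from seqaffinity import complex_kernel, sw_kernel

        shared_l, shared_r = random_sequence(rng, 40, 40), random_sequence(rng, 40, 40)
        exact = make_complex("T1", [shared_l], [shared_r], delta_g=-12.0)
        other = make_complex("T2", [random_sequence(rng, 40, 40)],
                             [random_sequence(rng, 40, 40)], delta_g=-5.0)
        query = make_complex("Q", [shared_l], [shared_r])
        # derived check: the exact match has the larger complex-level similarity
        sim_exact = complex_kernel(query, exact, sw_kernel)
        sim_other = complex_kernel(query, other, sw_kernel)
        assert sim_exact > sim_other
        model = HomologyNearestNeighbor().fit([other, exact])
        assert model.predict([query])[0] == -12.0

    def test_ties_broken_by_training_order(self):
        a = make_complex("T1", ["MKVMKV"], ["ACDACD"], delta_g=-6.0)
        b = make_complex("T2", ["MKVMKV"], ["ACDACD"], delta_g=-11.0)
        model = HomologyNearestNeighbor().fit([a, b])
        query = make_complex("Q", ["MKVMKV"], ["ACDACD"])
        assert model.predict([query])[0] == -6.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            HomologyNearestNeighbor().fit([])


class TestSerialization:
    def test_round_trip_preserves_predictions_bit_for_bit(self, rng, tmp_path):
        X, y, _ = linear_data(rng)
        est = AffinityRegressor(model="olsr").fit(X, y)
        path = tmp_path / "model.pkl"
        save_model(est, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.predict(X), est.predict(X))

    def test_version_mismatch_refused(self, rng, tmp_path):
        import pickle

        path = tmp_path / "model.pkl"
        with open(path, "wb") as fh:
            pickle.dump({"format": "seqaffinity-model", "version": 99, "estimator": None}, fh)
        with pytest.raises(ValueError, match="version"):
            load_model(path)

    def test_foreign_pickle_refused(self, tmp_path):
        import pickle

        path = tmp_path / "other.pkl"
        with open(path, "wb") as fh:
            pickle.dump({"something": 1}, fh)
        with pytest.raises(ValueError, match="not a seqaffinity model"):
            load_model(path)
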