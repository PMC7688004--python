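"""Regression estimators behind a single train/predict contract.

Three learner families are exposed, all scikit-learn estimators:

* :class:`AffinityRegressor` — explicit-feature models: ordinary least
  squares (minimum-norm on rank-deficient designs), linear/RBF support vector
  regression, and random-forest regression, with the unit-norm +
  standardization scaling fitted on the training rows and hyperparameters
  chosen by an inner grid search.
* :class:`KernelAffinityRegressor` — support vector regression on a
  precomputed (PSD-corrected) complex-level Gram matrix.
* :class:`HomologyNearestNeighbor` — the sequence-homology baseline: predict
  the affinity of the most Smith-Waterman-similar training complex.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, ParameterGrid
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .complexes import complex_kernel
from .kernels import AlignmentParams, GramMatrix, psd_correct, sw_kernel
from .scaling import UnitNormStandardScaler

logger = logging.getLogger(__name__)

MODEL_KINDS = ("olsr", "svr_linear", "svr_rbf", "rfr")

#: Default hyperparameter grids (log-spaced; configurable, not tuned facts).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "olsr": {},
    "svr_linear": {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0],
        "epsilon": [0.001, 0.01, 0.1, 0.5, 1.0],
    },
    "svr_rbf": {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0],
        "epsilon": [0.001, 0.01, 0.1, 0.5, 1.0],
        # 'auto' is the reciprocal-dimension heuristic 1/n_features
        "gamma": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, "auto"],
    },
    "rfr": {
        "n_estimators": [100, 200, 500],
        "min_samples_split": [2, 5, 10],
    },
    "svr_precomputed": {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0],
        "epsilon": [0.001, 0.01, 0.1, 0.5, 1.0],
    },
}

MODEL_FILE_FORMAT = "seqaffinity-model"
MODEL_FILE_VERSION = 1


def _base_estimator(kind: str, random_state: int):
    if kind == "olsr":
        return LinearRegression()
    if kind == "svr_linear":
        return SVR(kernel="linear")
    if kind == "svr_rbf":
        return SVR(kernel="rbf")
    if kind == "rfr":
        return RandomForestRegressor(random_state=random_state)
    if kind == "svr_precomputed":
        return SVR(kernel="precomputed")
    raise ValueError(f"unknown model kind {kind!r}; valid: {MODEL_KINDS}")


def select_hyperparameters(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    param_grid: dict,
    inner_cv: int = 5,
    random_state: int = 0,
):
    """Exhaustive grid search by inner k-fold CV on the training fold.

    Returns ``(fitted_estimator, selected_params)``.  A singleton (or empty)
    grid is applied directly without cross-validation; the setting minimizing
    mean inner RMSE wins, ties broken by grid order.  If the requested fold
    count exceeds the number of training rows it is reduced with a warning.
    """
    candidates = list(ParameterGrid(param_grid)) if param_grid else [{}]
    n = len(y)
    if len(candidates) == 1:
        est = clone(estimator).set_params(**candidates[0])
        est.fit(X, y)
        return est, candidates[0]
    n_splits = min(inner_cv, n)
    if n_splits < inner_cv:
        warnings.warn(
            f"inner CV folds reduced from {inner_cv} to {n_splits} "
            f"(only {n} training rows)",
            stacklevel=2,
        )
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    search = GridSearchCV(
        clone(estimator),
        param_grid,
        cv=cv,
        scoring="neg_root_mean_squared_error",
        refit=True,
        n_jobs=None,
    )
    search.fit(X, y)
    return search.best_estimator_, search.best_params_


class AffinityRegressor(RegressorMixin, BaseEstimator):
    """Explicit-feature binding-affinity regressor ``f(c) = w^T psi(c) + b``
    (or a random forest for the nonlinear kind).

    Parameters
    ----------
    model : {'olsr', 'svr_linear', 'svr_rbf', 'rfr'}
    param_grid : dict | None
        Hyperparameter grid; ``None`` selects the default grid for the kind,
        ``{}`` disables the search.
    inner_cv : int
        Folds of the inner model-selection CV (on the training rows only).
    scale : bool
        Apply unit-norm + standardization scaling (fit on training rows).
    """

    def __init__(
        self,
        model: str = "svr_rbf",
        param_grid: dict | None = None,
        inner_cv: int = 5,
        random_state: int = 0,
        scale: bool = True,
    ):
        self.model = model
        self.param_grid = param_grid
        self.inner_cv = inner_cv
        self.random_state = random_state
        self.scale = scale

    def fit(self, X, y) -> "AffinityRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError(f"inconsistent shapes X{X.shape}, y({len(y)},)")
        if len(y) < 2:
            raise ValueError("need at least 2 training complexes")
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model!r}; valid: {MODEL_KINDS}")
        self.scaler_ = UnitNormStandardScaler().fit(X) if self.scale else None
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        grid = DEFAULT_GRIDS[self.model] if self.param_grid is None else self.param_grid
        base = _base_estimator(self.model, self.random_state)
        self.model_, self.best_params_ = select_hyperparameters(
            base, Xs, y, grid, inner_cv=self.inner_cv, random_state=self.random_state
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected shape (n, {self.n_features_in_}), got {X.shape}")
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        return np.asarray(self.model_.predict(Xs), dtype=float)


class KernelAffinityRegressor(RegressorMixin, BaseEstimator):
    """Support vector regression on a precomputed complex-level Gram matrix.

    ``fit`` takes the square training Gram (a :class:`GramMatrix` or array)
    and applies the diagonal-shift PSD correction when needed; ``predict``
    takes cross-kernel rows ``K(test, train)``, which the diagonal shift does
    not alter.
    """

    def __init__(
        self,
        param_grid: dict | None = None,
        inner_cv: int = 5,
        random_state: int = 0,
        psd_correction: bool = True,
    ):
        self.param_grid = param_grid
        self.inner_cv = inner_cv
        self.random_state = random_state
        self.psd_correction = psd_correction

    def fit(self, G, y) -> "KernelAffinityRegressor":
        values = G.values if isinstance(G, GramMatrix) else np.asarray(G, dtype=float)
        y = np.asarray(y, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"training Gram must be square, got {values.shape}")
        if len(y) != values.shape[0]:
            raise ValueError("Gram size and label count differ")
        if len(y) < 2:
            raise ValueError("need at least 2 training complexes")
        tol = 1e-9 * max(1.0, float(np.abs(values).max()))
        if not np.allclose(values, values.T, atol=tol, rtol=1e-9):
            raise ValueError("training Gram must be symmetric")
        lam_min = float(np.linalg.eigvalsh((values + values.T) / 2.0).min())
        if self.psd_correction:
            if lam_min < 0:
                values = psd_correct(values)
            self.lambda_min_removed_ = min(lam_min, 0.0)
        else:
            if lam_min < -1e-8:
                raise ValueError(
                    f"Gram matrix is not PSD (lambda_min={lam_min:.3g}) and "
                    "psd_correction is disabled"
                )
            self.lambda_min_removed_ = 0.0
        grid = (
            DEFAULT_GRIDS["svr_precomputed"] if self.param_grid is None else self.param_grid
        )
        self.model_, self.best_params_ = select_hyperparameters(
            _base_estimator("svr_precomputed", self.random_state),
            values,
            y,
            grid,
            inner_cv=self.inner_cv,
            random_state=self.random_state,
        )
        self.n_train_ = values.shape[0]
        return self

    def predict(self, G_cross) -> np.ndarray:
        check_is_fitted(self, "model_")
        values = np.asarray(
            G_cross.values if isinstance(G_cross, GramMatrix) else G_cross, dtype=float
        )
        if values.ndim != 2 or values.shape[1] != self.n_train_:
            raise ValueError(
                f"cross-kernel rows must have shape (n_test, {self.n_train_}), "
                f"got {values.shape}"
            )
        return np.asarray(self.model_.predict(values), dtype=float)


class HomologyNearestNeighbor(RegressorMixin, BaseEstimator):
    """Sequence-homology baseline: affinity of the closest training homolog.

    Similarity between complexes is the chain-pair-averaged Smith-Waterman
    alignment score (BLOSUM62, gap open 11, extend 1).  Ties are broken by
    training-set order.
    """

    def __init__(self, alignment_params: AlignmentParams | None = None, pairing: str = "all"):
        self.alignment_params = alignment_params
        self.pairing = pairing

    def fit(self, X, y=None) -> "HomologyNearestNeighbor":
        complexes = list(X)
        if not complexes:
            raise ValueError("training set must be non-empty")
        if y is None:
            y = [c.delta_g for c in complexes]
            if any(v is None for v in y):
                raise ValueError("all training complexes need delta_g labels")
        y = np.asarray(y, dtype=float)
        if len(y) != len(complexes):
            raise ValueError("label count does not match training complexes")
        self.train_complexes_ = complexes
        self.y_ = y
        self._params = self.alignment_params or AlignmentParams()
        self._cache: dict[tuple[str, str], float] = {}
        return self

    def _chain_kernel(self, q, q2) -> float:
        key = (q.id, q2.id) if q.id <= q2.id else (q2.id, q.id)
        if key not in self._cache:
            self._cache[key] = sw_kernel(q, q2, self._params)
        return self._cache[key]

    def similarities(self, query) -> np.ndarray:
        """Complex-level SW similarity of one query to every training complex."""
        check_is_fitted(self, "train_complexes_")
        return np.array(
            [
                complex_kernel(query, t, self._chain_kernel, pairing=self.pairing)
                for t in self.train_complexes_
            ]
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "train_complexes_")
        preds = []
        for query in X:
            sims = self.similarities(query)
            preds.append(self.y_[int(np.argmax(sims))])  # argmax -> first max
        return np.array(preds)


# ---------------------------------------------------------------------------
# Serialization

def save_model(estimator, path: str | Path) -> None:
    """Serialize a fitted estimator with a format/version tag."""
    payload = {
        "format": MODEL_FILE_FORMAT,
        "version": MODEL_FILE_VERSION,
        "estimator": estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path):
    """Load a model file, refusing mismatched formats or versions."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FILE_FORMAT:
        raise ValueError(f"{path}: not a seqaffinity model file")
    if payload.get("version") != MODEL_FILE_VERSION:
        raise ValueError(
            f"{path}: model file version {payload.get('version')} "
            f"!= supported {MODEL_FILE_VERSION}"
        )
    return payload["estimator"]
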