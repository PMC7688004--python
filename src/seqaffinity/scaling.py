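"""Feature scaling: per-sample unit norm followed by column standardization.

Rows are first scaled to unit L2 norm (all-zero rows are passed through
unchanged), then each column is standardized to zero mean and unit standard
deviation using statistics learned on the training rows only; constant
columns keep a scale of 1 so they map to zero rather than NaN.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def _unit_norm_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


class UnitNormStandardScaler(TransformerMixin, BaseEstimator):
    """Unit-norm each sample, then standardize each feature column."""

    def fit(self, X, y=None) -> "UnitNormStandardScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-d feature matrix, got shape {X.shape}")
        Xn = _unit_norm_rows(X)
        self.mean_ = Xn.mean(axis=0)
        scale = Xn.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected shape (n, {self.n_features_in_}), got {X.shape}"
            )
        return (_unit_norm_rows(X) - self.mean_) / self.scale_
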