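"""Leave-one-complex-out evaluation, metrics, and the homology baseline.

In leave-one-complex-out (LOCO) cross-validation every complex is predicted
by a model fitted on the other ``N - 1`` complexes; scaling statistics and
hyperparameters are re-learned inside each training fold, so no test-complex
statistic leaks into training.  Aggregates are root-mean-squared error (RMSE,
kcal/mol) and the Pearson correlation between predicted and experimental
binding free energies with its two-sided p-value (t statistic, N-2 degrees of
freedom).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import LeaveOneOut

from .complexes import ComplexFeaturizer, complex_gram
from .descriptors import CompositeConfig
from .features import CHAIN_DESCRIPTORS
from .io import ComplexDataset, ProteinComplex
from .kernels import (
    AlignmentParams,
    MismatchParams,
    la_kernel,
    mismatch_kernel,
    sw_kernel,
)
from .models import (
    AffinityRegressor,
    HomologyNearestNeighbor,
    KernelAffinityRegressor,
)

logger = logging.getLogger(__name__)

KERNEL_NAMES = ("sw", "la", "mm")


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pearson(y_true, y_pred) -> tuple[float, float]:
    """Pearson r with two-sided p-value; (nan, nan) when either input has
    zero variance (never silently 0)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("pearson needs two equal-length vectors of length >= 2")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        logger.warning("pearson undefined: zero variance input; reporting NaN")
        return float("nan"), float("nan")
    if y_true.size < 3:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
        return r, float("nan")
    r, p = stats.pearsonr(y_true, y_pred)
    return float(r), float(p)


@dataclass
class EvaluationResult:
    """Per-complex LOCO predictions plus aggregate metrics."""

    per_complex: pd.DataFrame  # complex_id, y_true, y_pred, abs_error
    rmse: float
    pearson_r: float
    p_value: float
    n: int
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, ids, y_true, y_pred, metadata=None) -> "EvaluationResult":
        y_true = np.asarray(y_true, dtype=float)
        y_pred = np.asarray(y_pred, dtype=float)
        table = pd.DataFrame(
            {
                "complex_id": list(ids),
                "y_true": y_true,
                "y_pred": y_pred,
                "abs_error": np.abs(y_true - y_pred),
            }
        )
        r, p = pearson(y_true, y_pred)
        return cls(
            per_complex=table,
            rmse=rmse(y_true, y_pred),
            pearson_r=r,
            p_value=p,
            n=len(table),
            metadata=dict(metadata or {}),
        )

    def write_csv(self, per_complex_path, aggregate_path) -> None:
        self.per_complex.to_csv(per_complex_path, index=False)
        agg = {"n": self.n, "rmse": self.rmse, "pearson_r": self.pearson_r,
               "p_value": self.p_value}
        agg.update({k: str(v) for k, v in self.metadata.items()})
        pd.DataFrame([agg]).to_csv(aggregate_path, index=False)


def error_histogram(result: EvaluationResult, bin_edges) -> np.ndarray:
    """Cumulative fraction of complexes with absolute error <= each edge."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be non-empty and strictly increasing")
    errors = result.per_complex["abs_error"].to_numpy()
    if errors.size == 0:
        raise ValueError("empty evaluation result")
    return np.array([(errors <= e).mean() for e in edges])


# ---------------------------------------------------------------------------
# LOCO drivers

def loco_predictions_features(X, y, estimator) -> np.ndarray:
    """One held-out prediction per row; the estimator is re-fit per fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = np.empty_like(y)
    for train_idx, test_idx in LeaveOneOut().split(X):
        est = clone(estimator)
        try:
            est.fit(X[train_idx], y[train_idx])
            preds[test_idx] = est.predict(X[test_idx])
        except Exception as exc:
            raise RuntimeError(f"LOCO fold {test_idx[0]} failed: {exc}") from exc
    return preds


def loco_predictions_kernel(G_values: np.ndarray, y, estimator) -> np.ndarray:
    """LOCO over a precomputed Gram: train on the fold submatrix (PSD-corrected
    inside the estimator), predict from the held-out cross-kernel row."""
    G_values = np.asarray(G_values, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = np.empty_like(y)
    for train_idx, test_idx in LeaveOneOut().split(G_values):
        est = clone(estimator)
        try:
            est.fit(G_values[np.ix_(train_idx, train_idx)], y[train_idx])
            preds[test_idx] = est.predict(G_values[np.ix_(test_idx, train_idx)])
        except Exception as exc:
            raise RuntimeError(f"LOCO fold {test_idx[0]} failed: {exc}") from exc
    return preds


def homology_baseline(
    train: ComplexDataset | list[ProteinComplex],
    query: ProteinComplex,
    params: AlignmentParams | None = None,
    pairing: str = "all",
) -> float:
    """Affinity of the training complex most similar to the query."""
    complexes = list(train)
    model = HomologyNearestNeighbor(alignment_params=params, pairing=pairing).fit(complexes)
    return float(model.predict([query])[0])


class _ChainKernel:
    """Picklable chain-kernel callable bound to its parameters."""

    def __init__(self, kernel: str, alignment: AlignmentParams, mismatch: MismatchParams):
        if kernel not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {kernel!r}; valid: {KERNEL_NAMES}")
        self.kernel = kernel
        self.alignment = alignment
        self.mismatch = mismatch

    def __call__(self, a, b) -> float:
        if self.kernel == "sw":
            return sw_kernel(a, b, self.alignment)
        if self.kernel == "la":
            return la_kernel(a, b, self.alignment)
        return mismatch_kernel(a, b, self.mismatch)


def _chain_kernel_fn(kernel: str, alignment: AlignmentParams, mismatch: MismatchParams):
    return _ChainKernel(kernel, alignment, mismatch)


def evaluate_loco(
    dataset: ComplexDataset,
    representation: str = "aac",
    model: str = "olsr",
    *,
    param_grid: dict | None = None,
    inner_cv: int = 5,
    random_state: int = 0,
    alignment: AlignmentParams | None = None,
    mismatch: MismatchParams | None = None,
    profiles=None,
    pssm_fallback: bool = True,
    composite_config: CompositeConfig | None = None,
    pairing: str = "all",
) -> EvaluationResult:
    """Run LOCO CV for one representation/model configuration.

    ``representation`` is an explicit descriptor ('aac', 'blosum', 'propy',
    'pssm', 'protparam'), a kernel name ('sw', 'la', 'mm' — evaluated with
    precomputed-kernel SVR regardless of ``model``), or 'homology' for the
    nearest-homolog baseline.
    """
    dataset.require_cv_ready(min_n=3)
    y = dataset.y
    ids = dataset.ids
    alignment = alignment or AlignmentParams()
    mismatch = mismatch or MismatchParams()
    metadata = {"representation": representation, "model": model, "n": len(dataset)}

    if representation == "homology":
        # Pairwise SW similarities are symmetric and involve no fitted
        # statistics, so the full matrix can be computed once; each complex is
        # then matched against the other N-1 only.
        g = complex_gram(
            dataset,
            lambda a, b: sw_kernel(a, b, alignment),
            kernel_name="sw",
            pairing=pairing,
        )
        preds = np.empty(len(y))
        sims = g.values.copy()
        np.fill_diagonal(sims, -np.inf)
        for i in range(len(y)):
            preds[i] = y[int(np.argmax(sims[i]))]
        metadata["model"] = "nearest_homolog"
        return EvaluationResult.from_predictions(ids, y, preds, metadata)

    if representation in KERNEL_NAMES:
        g = complex_gram(
            dataset,
            _chain_kernel_fn(representation, alignment, mismatch),
            kernel_name=representation,
            pairing=pairing,
        )
        estimator = KernelAffinityRegressor(
            param_grid=param_grid, inner_cv=inner_cv, random_state=random_state
        )
        preds = loco_predictions_kernel(g.values, y, estimator)
        metadata["model"] = "svr_precomputed"
        return EvaluationResult.from_predictions(ids, y, preds, metadata)

    if representation in CHAIN_DESCRIPTORS:
        featurizer = ComplexFeaturizer(
            descriptor=representation,
            profiles=profiles,
            pssm_fallback=pssm_fallback,
            composite_config=composite_config,
        ).fit()
        X = featurizer.transform(dataset)
        estimator = AffinityRegressor(
            model=model,
            param_grid=param_grid,
            inner_cv=inner_cv,
            random_state=random_state,
        )
        preds = loco_predictions_features(X, y, estimator)
        metadata.update(featurizer.meta_)
        return EvaluationResult.from_predictions(ids, y, preds, metadata)

    raise ValueError(
        f"unknown representation {representation!r}; valid: "
        f"{CHAIN_DESCRIPTORS + KERNEL_NAMES + ('homology',)}"
    )


# ---------------------------------------------------------------------------
# Benchmark-style sweep

SWEEP_EXPLICIT_MODELS = ("olsr", "rfr", "svr_rbf")


def sweep(
    dataset: ComplexDataset,
    *,
    grids: dict[str, dict] | None = None,
    inner_cv: int = 5,
    random_state: int = 0,
    profiles=None,
    alignment: AlignmentParams | None = None,
    mismatch: MismatchParams | None = None,
) -> pd.DataFrame:
    """Evaluate {5 explicit descriptors x 3 models} + {3 kernels x SVR}.

    Kernel representations are restricted to precomputed-kernel SVR (tree and
    plain least-squares learners consume explicit features only).  Returns one
    row per configuration (18 rows) mirroring a benchmark results table.
    """
    grids = grids or {}
    rows = []
    for descriptor in CHAIN_DESCRIPTORS:
        for model in SWEEP_EXPLICIT_MODELS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = evaluate_loco(
                    dataset,
                    representation=descriptor,
                    model=model,
                    param_grid=grids.get(model),
                    inner_cv=inner_cv,
                    random_state=random_state,
                    profiles=profiles,
                )
            rows.append(_sweep_row(result, descriptor, model, "explicit"))
    for kernel in KERNEL_NAMES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = evaluate_loco(
                dataset,
                representation=kernel,
                param_grid=grids.get("svr_precomputed"),
                inner_cv=inner_cv,
                random_state=random_state,
                alignment=alignment,
                mismatch=mismatch,
            )
        rows.append(_sweep_row(result, kernel, "svr_precomputed", "kernel"))
    return pd.DataFrame(rows)


def _sweep_row(result: EvaluationResult, representation, model, kind) -> dict:
    return {
        "representation": representation,
        "kind": kind,
        "model": model,
        "pearson_r": result.pearson_r,
        "p_value": result.p_value,
        "rmse": result.rmse,
        "n": result.n,
    }
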