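"""End-to-end train/predict pipeline over a labelled complex dataset.

Bundles the representation (explicit descriptor, precomputed string kernel,
or homology baseline) with the fitted regressor and whatever state prediction
needs (the training complexes, for kernel and homology representations), so a
trained predictor can be serialized and later applied to new complexes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .complexes import ComplexFeaturizer, complex_gram, complex_kernel
from .descriptors import CompositeConfig
from .evaluation import KERNEL_NAMES, _chain_kernel_fn
from .features import CHAIN_DESCRIPTORS
from .io import ComplexDataset, ProteinComplex
from .kernels import AlignmentParams, MismatchParams
from .models import AffinityRegressor, HomologyNearestNeighbor, KernelAffinityRegressor


class AffinityPipeline(BaseEstimator):
    """Fit a representation + regressor on a dataset; predict new complexes."""

    def __init__(
        self,
        representation: str = "aac",
        model: str = "olsr",
        param_grid: dict | None = None,
        inner_cv: int = 5,
        random_state: int = 0,
        alignment: AlignmentParams | None = None,
        mismatch: MismatchParams | None = None,
        profiles=None,
        pssm_fallback: bool = True,
        composite_config: CompositeConfig | None = None,
        pairing: str = "all",
    ):
        self.representation = representation
        self.model = model
        self.param_grid = param_grid
        self.inner_cv = inner_cv
        self.random_state = random_state
        self.alignment = alignment
        self.mismatch = mismatch
        self.profiles = profiles
        self.pssm_fallback = pssm_fallback
        self.composite_config = composite_config
        self.pairing = pairing

    def fit(self, dataset: ComplexDataset | list[ProteinComplex], y=None) -> "AffinityPipeline":
        complexes = list(dataset)
        if y is None:
            y = np.array([c.delta_g for c in complexes], dtype=float)
            if np.any(np.isnan(y)):
                raise ValueError("all training complexes need delta_g labels")
        else:
            y = np.asarray(y, dtype=float)
        alignment = self.alignment or AlignmentParams()
        mismatch = self.mismatch or MismatchParams()

        if self.representation == "homology":
            self.estimator_ = HomologyNearestNeighbor(
                alignment_params=alignment, pairing=self.pairing
            ).fit(complexes, y)
        elif self.representation in KERNEL_NAMES:
            self.train_complexes_ = complexes
            self._chain_kernel_ = _chain_kernel_fn(self.representation, alignment, mismatch)
            g = complex_gram(
                complexes, self._chain_kernel_,
                kernel_name=self.representation, pairing=self.pairing,
            )
            self.estimator_ = KernelAffinityRegressor(
                param_grid=self.param_grid,
                inner_cv=self.inner_cv,
                random_state=self.random_state,
            ).fit(g.values, y)
        elif self.representation in CHAIN_DESCRIPTORS:
            self.featurizer_ = ComplexFeaturizer(
                descriptor=self.representation,
                profiles=self.profiles,
                pssm_fallback=self.pssm_fallback,
                composite_config=self.composite_config,
            ).fit()
            X = self.featurizer_.transform(complexes)
            self.estimator_ = AffinityRegressor(
                model=self.model,
                param_grid=self.param_grid,
                inner_cv=self.inner_cv,
                random_state=self.random_state,
            ).fit(X, y)
        else:
            raise ValueError(
                f"unknown representation {self.representation!r}; valid: "
                f"{CHAIN_DESCRIPTORS + KERNEL_NAMES + ('homology',)}"
            )
        return self

    def predict(self, complexes) -> np.ndarray:
        complexes = list(complexes)
        if self.representation == "homology":
            return self.estimator_.predict(complexes)
        if self.representation in KERNEL_NAMES:
            rows = np.array(
                [
                    [
                        complex_kernel(q, t, self._chain_kernel_, pairing=self.pairing)
                        for t in self.train_complexes_
                    ]
                    for q in complexes
                ]
            )
            return self.estimator_.predict(rows)
        return self.estimator_.predict(self.featurizer_.transform(complexes))
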