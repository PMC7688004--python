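"""Lifting chain-level features and kernels to the complex level.

A complex feature vector stacks the ligand-chain mean of a chain descriptor on
top of the receptor-chain mean (ligand block first, so swapping ligand and
receptor changes the representation).  A complex-level kernel averages the
chain-level kernel over chain pairs drawn from the two complexes.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import SubstitutionMatrix
from .descriptors import CompositeConfig
from .features import descriptor_feature_names, get_chain_featurizer
from .io import ProteinChain, ProteinComplex, PSSMProfile
from .kernels import GramMatrix


def complex_features(
    c: ProteinComplex, featurizer: Callable[[ProteinChain], np.ndarray]
) -> np.ndarray:
    """[mean over ligand chains; mean over receptor chains] of a chain descriptor."""

    def side_mean(chains) -> np.ndarray:
        rows = []
        for ch in chains:
            try:
                rows.append(np.asarray(featurizer(ch), dtype=float))
            except Exception as exc:
                raise RuntimeError(
                    f"featurizer failed for chain {ch.id!r} of complex {c.id!r}: {exc}"
                ) from exc
        return np.mean(rows, axis=0)

    return np.concatenate([side_mean(c.ligand), side_mean(c.receptor)])


class ComplexFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping protein complexes to complex-level descriptors.

    Parameters
    ----------
    descriptor : str
        Chain descriptor registry name ('aac', 'blosum', 'propy', 'pssm',
        'protparam').
    profiles : dict[str, PSSMProfile] | None
        Per-chain-id PSSM profiles for ``descriptor='pssm'``.
    pssm_fallback : bool
        Substitute BLOSUM62 columns for chains without a profile.
    """

    def __init__(
        self,
        descriptor: str = "aac",
        profiles: dict[str, PSSMProfile] | None = None,
        pssm_fallback: bool = True,
        composite_config: CompositeConfig | None = None,
        substitution: SubstitutionMatrix | None = None,
    ):
        self.descriptor = descriptor
        self.profiles = profiles
        self.pssm_fallback = pssm_fallback
        self.composite_config = composite_config
        self.substitution = substitution

    def fit(self, X=None, y=None) -> "ComplexFeaturizer":
        featurizer, meta = get_chain_featurizer(
            self.descriptor,
            profiles=self.profiles,
            pssm_fallback=self.pssm_fallback,
            composite_config=self.composite_config,
            substitution=self.substitution,
        )
        self.chain_featurizer_ = featurizer
        self.meta_ = meta
        chain_names = descriptor_feature_names(self.descriptor, self.composite_config)
        self.feature_names_ = [f"ligand_{n}" for n in chain_names] + [
            f"receptor_{n}" for n in chain_names
        ]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "chain_featurizer_"):
            self.fit()
        complexes = list(X)
        return np.vstack([complex_features(c, self.chain_featurizer_) for c in complexes])

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.asarray(self.feature_names_, dtype=object)


def complex_kernel(
    c: ProteinComplex,
    c2: ProteinComplex,
    kernel: Callable[[ProteinChain, ProteinChain], float],
    pairing: str = "all",
) -> float:
    """Chain-pair-averaged kernel between two complexes.

    ``pairing='all'`` (default) averages over every cross-complex chain pair,
    counting ligand and receptor chains alike.  ``pairing='matched'`` averages
    the ligand-ligand and receptor-receptor means instead.
    """

    def block_mean(chains_a, chains_b) -> float:
        total = 0.0
        for q in chains_a:
            for q2 in chains_b:
                try:
                    total += kernel(q, q2)
                except Exception as exc:
                    raise RuntimeError(
                        f"chain kernel failed for pair ({q.id!r} of {c.id!r}, "
                        f"{q2.id!r} of {c2.id!r}): {exc}"
                    ) from exc
        return total / (len(chains_a) * len(chains_b))

    if pairing == "all":
        return block_mean(c.chains, c2.chains)
    if pairing == "matched":
        return 0.5 * (block_mean(c.ligand, c2.ligand) + block_mean(c.receptor, c2.receptor))
    raise ValueError(f"unknown pairing {pairing!r}; use 'all' or 'matched'")


def complex_gram(
    complexes,
    kernel: Callable[[ProteinChain, ProteinChain], float],
    kernel_name: str = "custom",
    pairing: str = "all",
    normalize: bool = False,
) -> GramMatrix:
    """Complex-level Gram matrix with chain-pair kernel values cached.

    Chains shared between complexes (common in affinity benchmarks) are only
    aligned once per unordered chain pair.
    """
    complexes = list(complexes)
    if not complexes:
        raise ValueError("complex_gram requires at least one complex")
    cache: dict[tuple[str, str], float] = {}

    def cached_kernel(q: ProteinChain, q2: ProteinChain) -> float:
        key = (q.id, q2.id) if q.id <= q2.id else (q2.id, q.id)
        if key not in cache:
            cache[key] = kernel(q, q2)
        return cache[key]

    n = len(complexes)
    values = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = complex_kernel(
                complexes[i], complexes[j], cached_kernel, pairing=pairing
            )
    g = GramMatrix(
        ids=tuple(c.id for c in complexes), values=values, kernel_name=kernel_name
    )
    if normalize:
        diag = np.sqrt(np.diag(g.values))
        if np.any(diag <= 0):
            raise ValueError("cosine normalization requires positive self-kernel values")
        g = GramMatrix(
            ids=g.ids,
            values=g.values / np.outer(diag, diag),
            kernel_name=f"{kernel_name}_cosine",
        )
    return g
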