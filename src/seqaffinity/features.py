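"""Explicit per-chain feature encoders.

Five descriptor families are exposed under short registry names:

``aac``
    Raw amino-acid counts (20-d).  Downstream models normalize rows to unit
    norm, so counts and frequencies are proportional there.
``blosum``
    Mean of the BLOSUM62 columns of the chain's residues (20-d).
``propy``
    Composite physicochemical descriptors (see :mod:`seqaffinity.descriptors`).
``pssm``
    Columnwise mean of a PSI-BLAST position-specific scoring matrix (20-d);
    without a profile it can fall back to the per-residue BLOSUM62 column,
    which makes it identical to ``blosum`` (flagged in metadata).
``protparam``
    Seven whole-chain physicochemical summaries: molecular weight (Da),
    aromaticity, instability index, isoelectric point, and helix/turn/sheet
    residue fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .alphabet import AMINO_ACIDS, SubstitutionMatrix, blosum62, encode_sequence
from .descriptors import (
    CompositeConfig,
    composite_descriptors,
    composite_dimension,
    composite_feature_names,
)
from .io import ProteinChain, PSSMProfile, associate_pssm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length chain or complex descriptor."""

    descriptor_name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"feature vector must be 1-d, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.descriptor_name}: non-finite feature entries")
        object.__setattr__(self, "values", v)

    @property
    def dimension(self) -> int:
        return self.values.size


def aac(chain: ProteinChain) -> FeatureVector:
    """Amino-acid occurrence counts; entries sum to the chain length."""
    counts = np.bincount(encode_sequence(chain.sequence), minlength=20).astype(float)
    return FeatureVector("aac", counts)


def blosum_avg(chain: ProteinChain, matrix: SubstitutionMatrix | None = None) -> FeatureVector:
    """Mean substitution-matrix column over the chain's residues."""
    matrix = matrix or blosum62()
    cols = matrix.scores[:, encode_sequence(chain.sequence)]  # (20, L)
    return FeatureVector(f"blosum_avg[{matrix.name}]", cols.mean(axis=1))


def pssm_avg(chain: ProteinChain, profile: PSSMProfile) -> FeatureVector:
    """Columnwise mean of the chain's per-residue log-odds profile."""
    associate_pssm(chain, profile)
    return FeatureVector("pssm_avg", profile.rows.mean(axis=0))


_PROTPARAM_NAMES = (
    "molecular_weight", "aromaticity", "instability_index", "isoelectric_point",
    "helix_fraction", "turn_fraction", "sheet_fraction",
)


def protparam(chain: ProteinChain) -> FeatureVector:
    """Whole-chain physicochemical summary (7-d).

    Aromaticity is the F/W/Y fraction; the instability index follows the
    Guruprasad dipeptide weights; the isoelectric point solves the
    Henderson-Hasselbalch charge balance; secondary-structure fractions are
    residue fractions of the conventional helix {V,I,Y,F,W,L}, turn {N,P,G,S}
    and sheet {E,M,A,L} sets.
    """
    pa = ProteinAnalysis(chain.sequence)
    helix, turn, sheet = pa.secondary_structure_fraction()
    values = np.array(
        [
            pa.molecular_weight(),
            pa.aromaticity(),
            pa.instability_index(),
            pa.isoelectric_point(),
            helix,
            turn,
            sheet,
        ]
    )
    return FeatureVector("protparam", values)


# ---------------------------------------------------------------------------
# Registry

CHAIN_DESCRIPTORS = ("aac", "blosum", "propy", "pssm", "protparam")


def descriptor_dimension(
    descriptor: str, composite_config: CompositeConfig | None = None
) -> int:
    if descriptor in ("aac", "blosum", "pssm"):
        return 20
    if descriptor == "protparam":
        return 7
    if descriptor == "propy":
        return composite_dimension(composite_config or CompositeConfig())
    raise ValueError(f"unknown descriptor {descriptor!r}; valid: {CHAIN_DESCRIPTORS}")


def descriptor_feature_names(
    descriptor: str, composite_config: CompositeConfig | None = None
) -> list[str]:
    if descriptor in ("aac", "blosum", "pssm"):
        return [f"{descriptor}_{aa}" for aa in AMINO_ACIDS]
    if descriptor == "protparam":
        return list(_PROTPARAM_NAMES)
    if descriptor == "propy":
        return composite_feature_names(composite_config or CompositeConfig())
    raise ValueError(f"unknown descriptor {descriptor!r}; valid: {CHAIN_DESCRIPTORS}")


# Featurizer callables are plain picklable classes so fitted transformers and
# trained pipelines can be serialized.
class _AacFeaturizer:
    def __call__(self, ch: ProteinChain) -> np.ndarray:
        return aac(ch).values


class _BlosumFeaturizer:
    def __init__(self, matrix: SubstitutionMatrix):
        self.matrix = matrix

    def __call__(self, ch: ProteinChain) -> np.ndarray:
        return blosum_avg(ch, self.matrix).values


class _ProtParamFeaturizer:
    def __call__(self, ch: ProteinChain) -> np.ndarray:
        return protparam(ch).values


class _CompositeFeaturizer:
    def __init__(self, config: CompositeConfig):
        self.config = config

    def __call__(self, ch: ProteinChain) -> np.ndarray:
        return composite_descriptors(ch, self.config)


class _PssmFeaturizer:
    def __init__(self, profiles, fallback: bool, matrix: SubstitutionMatrix, meta: dict):
        self.profiles = profiles
        self.fallback = fallback
        self.matrix = matrix
        self.meta = meta

    def __call__(self, ch: ProteinChain) -> np.ndarray:
        prof = self.profiles.get(ch.id)
        if prof is not None:
            return pssm_avg(ch, prof).values
        if not self.fallback:
            raise KeyError(f"no PSSM profile for chain {ch.id!r} and fallback disabled")
        if not self.meta["pssm_fallback_used"]:
            logger.warning(
                "no PSSM profile for chain %r (and possibly others); "
                "substituting BLOSUM62 columns", ch.id,
            )
        self.meta["pssm_fallback_used"] = True
        return blosum_avg(ch, self.matrix).values


def get_chain_featurizer(
    descriptor: str,
    *,
    profiles: dict[str, PSSMProfile] | None = None,
    pssm_fallback: bool = True,
    composite_config: CompositeConfig | None = None,
    substitution: SubstitutionMatrix | None = None,
) -> tuple[Callable[[ProteinChain], np.ndarray], dict]:
    """Resolve a registry name to a ``chain -> ndarray`` callable.

    Returns the callable plus a metadata dict (descriptor, dimension, and
    whether the PSSM/BLOSUM fallback is active).
    """
    meta = {
        "descriptor": descriptor,
        "dimension": descriptor_dimension(descriptor, composite_config),
        "pssm_fallback_used": False,
    }
    if descriptor == "aac":
        return _AacFeaturizer(), meta
    if descriptor == "blosum":
        return _BlosumFeaturizer(substitution or blosum62()), meta
    if descriptor == "protparam":
        return _ProtParamFeaturizer(), meta
    if descriptor == "propy":
        return _CompositeFeaturizer(composite_config or CompositeConfig()), meta
    if descriptor == "pssm":
        return (
            _PssmFeaturizer(profiles or {}, pssm_fallback, substitution or blosum62(), meta),
            meta,
        )
    raise ValueError(f"unknown descriptor {descriptor!r}; valid: {CHAIN_DESCRIPTORS}")
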