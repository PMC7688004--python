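"""Composite physicochemical sequence descriptors.

Implements the classic families used for sequence-derived structural features:
amino-acid composition (frequencies), normalized Moreau-Broto / Moran / Geary
autocorrelations over a fixed panel of physicochemical property scales,
composition/transition/distribution (CTD) descriptors over the Dubchak
three-class attribute groupings, sequence-order-coupling numbers, Chou
quasi-sequence-order descriptors, and type-I pseudo-amino-acid composition.

All families are deterministic functions of the sequence.  For chains shorter
than ``max_lag + 1`` residues the lag range is truncated to ``len - 1`` (with a
logged warning) and the remaining entries zero-filled, so the descriptor
dimension is constant across chains for a fixed configuration.

The property panel consists of eight published per-residue scales
(Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity, Zamyatnin residue
volume, average residue mass, Grantham polarity, free-residue isoelectric
point, and the Chou-Fasman helix and sheet propensities), z-normalized over
the 20 residues before use.  The residue distance used by the sequence-order
families is the Euclidean distance in this z-scaled property space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .alphabet import AMINO_ACIDS, encode_sequence
from .io import ProteinChain

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Property scales (order: ACDEFGHIKLMNPQRSTVWY)

_SCALES: dict[str, dict[str, float]] = {
    "kd_hydropathy": {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
        "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
        "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
        "W": -0.9, "Y": -1.3,
    },
    "hw_hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3,
    },
    "residue_volume": {
        "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
        "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
        "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
        "W": 227.8, "Y": 193.6,
    },
    "residue_mass": {
        "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
        "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
        "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
        "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
    },
    "polarity": {
        "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
        "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
        "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
        "W": 5.4, "Y": 6.2,
    },
    "isoelectric_point": {
        "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
        "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
        "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96,
        "W": 5.89, "Y": 5.66,
    },
    "cf_helix_propensity": {
        "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
        "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
        "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
        "W": 1.08, "Y": 0.69,
    },
    "cf_sheet_propensity": {
        "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
        "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30, "M": 1.05, "N": 0.89,
        "P": 0.55, "Q": 1.10, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.70,
        "W": 1.37, "Y": 1.47,
    },
}

SCALE_NAMES: tuple[str, ...] = tuple(_SCALES)


def _scale_matrix() -> np.ndarray:
    """(8, 20) raw property values in alphabet order."""
    return np.array([[_SCALES[s][aa] for aa in AMINO_ACIDS] for s in SCALE_NAMES])


@lru_cache(maxsize=1)
def _normalized_scales() -> np.ndarray:
    """(8, 20) z-normalized property values (population statistics)."""
    raw = _scale_matrix()
    return (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)


@lru_cache(maxsize=1)
def residue_distance_matrix() -> np.ndarray:
    """20x20 Euclidean residue distance in the z-scaled 8-property space."""
    z = _normalized_scales()  # (8, 20)
    diff = z[:, :, None] - z[:, None, :]
    return np.sqrt((diff**2).sum(axis=0))


# Dubchak three-class attribute groupings for CTD.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
}

# Type-I pseudo-AAC property triple: hydropathy, hydrophilicity, side-chain mass.
_GLYCINE_RESIDUE_MASS = _SCALES["residue_mass"]["G"]


@lru_cache(maxsize=1)
def _paac_properties() -> np.ndarray:
    """(3, 20) z-normalized hydropathy, hydrophilicity, side-chain mass."""
    h1 = np.array([_SCALES["kd_hydropathy"][aa] for aa in AMINO_ACIDS])
    h2 = np.array([_SCALES["hw_hydrophilicity"][aa] for aa in AMINO_ACIDS])
    mass = np.array(
        [_SCALES["residue_mass"][aa] - _GLYCINE_RESIDUE_MASS + 1.01 for aa in AMINO_ACIDS]
    )
    props = np.vstack([h1, h2, mass])
    return (props - props.mean(axis=1, keepdims=True)) / props.std(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Configuration and registry

FAMILY_ORDER = ("aac", "moreau_broto", "moran", "geary", "ctd", "socn", "qso", "paac")


@dataclass(frozen=True)
class CompositeConfig:
    """Descriptor-set selection for :func:`composite_descriptors`."""

    families: tuple[str, ...] = FAMILY_ORDER
    max_lag: int = 30
    qso_weight: float = 0.1
    paac_lambda: int = 30
    paac_weight: float = 0.05

    def __post_init__(self) -> None:
        unknown = [f for f in self.families if f not in FAMILY_ORDER]
        if unknown:
            raise ValueError(f"unknown descriptor families {unknown}; valid: {FAMILY_ORDER}")
        if self.max_lag < 1 or self.paac_lambda < 1:
            raise ValueError("max_lag and paac_lambda must be >= 1")


def family_dimension(family: str, config: CompositeConfig) -> int:
    n_scales = len(SCALE_NAMES)
    return {
        "aac": 20,
        "moreau_broto": n_scales * config.max_lag,
        "moran": n_scales * config.max_lag,
        "geary": n_scales * config.max_lag,
        "ctd": len(CTD_GROUPS) * (3 + 3 + 15),
        "socn": config.max_lag,
        "qso": 20 + config.max_lag,
        "paac": 20 + config.paac_lambda,
    }[family]


def composite_dimension(config: CompositeConfig = CompositeConfig()) -> int:
    """Total dimension for a configuration (1017 with defaults)."""
    return sum(family_dimension(f, config) for f in ordered_families(config))


def ordered_families(config: CompositeConfig) -> tuple[str, ...]:
    return tuple(f for f in FAMILY_ORDER if f in config.families)


def composite_feature_names(config: CompositeConfig = CompositeConfig()) -> list[str]:
    names: list[str] = []
    for fam in ordered_families(config):
        if fam == "aac":
            names += [f"aac_{aa}" for aa in AMINO_ACIDS]
        elif fam in ("moreau_broto", "moran", "geary"):
            names += [
                f"{fam}_{scale}_lag{d}"
                for scale in SCALE_NAMES
                for d in range(1, config.max_lag + 1)
            ]
        elif fam == "ctd":
            for attr in CTD_GROUPS:
                names += [f"ctd_comp_{attr}_c{g}" for g in (1, 2, 3)]
                names += [f"ctd_trans_{attr}_{p}" for p in ("12", "13", "23")]
                names += [
                    f"ctd_dist_{attr}_c{g}_q{q}"
                    for g in (1, 2, 3)
                    for q in ("first", "25", "50", "75", "100")
                ]
        elif fam == "socn":
            names += [f"socn_lag{d}" for d in range(1, config.max_lag + 1)]
        elif fam == "qso":
            names += [f"qso_{aa}" for aa in AMINO_ACIDS]
            names += [f"qso_lag{d}" for d in range(1, config.max_lag + 1)]
        elif fam == "paac":
            names += [f"paac_{aa}" for aa in AMINO_ACIDS]
            names += [f"paac_lag{d}" for d in range(1, config.paac_lambda + 1)]
    return names


# ---------------------------------------------------------------------------
# Family implementations

def _autocorrelations(idx: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moreau-Broto / Moran / Geary blocks, each (n_scales, max_lag)."""
    z = _normalized_scales()[:, idx]  # (S, N) per-residue property traces
    n_scales, n = z.shape
    mb = np.zeros((n_scales, max_lag))
    moran = np.zeros((n_scales, max_lag))
    geary = np.zeros((n_scales, max_lag))
    mean = z.mean(axis=1, keepdims=True)
    dev = z - mean
    var_pop = (dev**2).mean(axis=1)  # Moran denominator (1/N)
    var_samp = (dev**2).sum(axis=1) / max(n - 1, 1)  # Geary denominator (1/(N-1))
    effective = min(max_lag, n - 1)
    for d in range(1, effective + 1):
        head, tail = z[:, :-d], z[:, d:]
        mb[:, d - 1] = (head * tail).mean(axis=1)
        num_moran = (dev[:, :-d] * dev[:, d:]).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            moran[:, d - 1] = np.where(var_pop > 1e-12, num_moran / var_pop, 0.0)
        num_geary = ((head - tail) ** 2).sum(axis=1) / (2 * (n - d))
        with np.errstate(invalid="ignore", divide="ignore"):
            geary[:, d - 1] = np.where(var_samp > 1e-12, num_geary / var_samp, 0.0)
    return mb, moran, geary


def _ctd(sequence: str) -> np.ndarray:
    n = len(sequence)
    out: list[float] = []
    for attr, groups in CTD_GROUPS.items():
        cls = np.array([1 if c in groups[0] else 2 if c in groups[1] else 3 for c in sequence])
        # composition
        out += [float(np.mean(cls == g)) for g in (1, 2, 3)]
        # transitions between distinct classes among adjacent residues
        if n > 1:
            pairs = list(zip(cls[:-1], cls[1:]))
            for a, b in ((1, 2), (1, 3), (2, 3)):
                cnt = sum(1 for p, q in pairs if (p, q) in ((a, b), (b, a)))
                out.append(cnt / (n - 1))
        else:
            out += [0.0, 0.0, 0.0]
        # distribution: residue positions (% of length) at which the first,
        # 25%, 50%, 75% and 100% of each class's occurrences are reached
        for g in (1, 2, 3):
            pos = np.flatnonzero(cls == g) + 1  # 1-based
            if pos.size == 0:
                out += [0.0] * 5
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = max(1, math.ceil(q * pos.size))
                out.append(pos[rank - 1] / n * 100.0)
    return np.array(out)


def _coupling_numbers(idx: np.ndarray, max_lag: int) -> np.ndarray:
    """tau_d = sum_i dist(s_i, s_{i+d})^2 for d = 1..max_lag (zero-filled)."""
    d2 = residue_distance_matrix() ** 2
    n = idx.size
    tau = np.zeros(max_lag)
    for d in range(1, min(max_lag, n - 1) + 1):
        tau[d - 1] = d2[idx[:-d], idx[d:]].sum()
    return tau


def _paac_theta(idx: np.ndarray, lam: int) -> np.ndarray:
    """Chou's sequence-order correlation factors theta_1..theta_lambda."""
    props = _paac_properties()[:, idx]  # (3, N)
    n = idx.size
    theta = np.zeros(lam)
    for d in range(1, min(lam, n - 1) + 1):
        diff = props[:, :-d] - props[:, d:]
        theta[d - 1] = (diff**2).mean(axis=0).mean()
    return theta


def composite_descriptors(
    chain: ProteinChain, config: CompositeConfig = CompositeConfig()
) -> np.ndarray:
    """Concatenated composite descriptor vector for one chain.

    Families appear in registry order (:data:`FAMILY_ORDER`); the total length
    equals :func:`composite_dimension` for every chain under a fixed config.
    """
    idx = encode_sequence(chain.sequence)
    n = idx.size
    max_needed = max(config.max_lag, config.paac_lambda)
    if n <= max_needed:
        logger.warning(
            "chain %r has %d residues (< max lag %d + 1); lag features truncated "
            "to %d lag(s) and zero-filled",
            chain.id, n, max_needed, max(n - 1, 0),
        )

    freqs = np.bincount(idx, minlength=20) / n
    blocks: list[np.ndarray] = []
    mb = moran = geary = None
    for fam in ordered_families(config):
        if fam == "aac":
            blocks.append(freqs)
        elif fam in ("moreau_broto", "moran", "geary"):
            if mb is None:
                mb, moran, geary = _autocorrelations(idx, config.max_lag)
            blocks.append({"moreau_broto": mb, "moran": moran, "geary": geary}[fam].ravel())
        elif fam == "ctd":
            blocks.append(_ctd(chain.sequence))
        elif fam == "socn":
            blocks.append(_coupling_numbers(idx, config.max_lag))
        elif fam == "qso":
            tau = _coupling_numbers(idx, config.max_lag)
            denom = freqs.sum() + config.qso_weight * tau.sum()
            blocks.append(np.concatenate([freqs / denom, config.qso_weight * tau / denom]))
        elif fam == "paac":
            theta = _paac_theta(idx, config.paac_lambda)
            denom = freqs.sum() + config.paac_weight * theta.sum()
            blocks.append(np.concatenate([freqs / denom, config.paac_weight * theta / denom]))
    vec = np.concatenate(blocks)
    if not np.all(np.isfinite(vec)):  # pragma: no cover - guarded by construction
        raise FloatingPointError(f"non-finite composite descriptor for chain {chain.id!r}")
    return vec
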