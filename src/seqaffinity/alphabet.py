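"""Canonical amino-acid alphabet, sequence sanitization, and substitution matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: The 20 canonical residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Conservative mappings for the common ambiguity/rare codes; everything else
# (including X) falls back to alanine.
_AMBIGUOUS_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K"}
_FALLBACK_RESIDUE = "A"


def sanitize_sequence(sequence: str, *, context: str = "") -> str:
    """Upper-case a raw sequence and map non-canonical residues onto the
    20-letter alphabet (B->D, Z->E, U->C, O->K, anything else -> A).

    A warning is logged whenever a residue had to be replaced.
    """
    seq = sequence.strip().upper()
    out = []
    replaced: dict[str, str] = {}
    for ch in seq:
        if ch in AA_INDEX:
            out.append(ch)
        elif ch in _AMBIGUOUS_MAP:
            out.append(_AMBIGUOUS_MAP[ch])
            replaced[ch] = _AMBIGUOUS_MAP[ch]
        else:
            out.append(_FALLBACK_RESIDUE)
            replaced[ch] = _FALLBACK_RESIDUE
    if replaced:
        logger.warning(
            "Non-canonical residues replaced%s: %s",
            f" in {context}" if context else "",
            ", ".join(f"{k}->{v}" for k, v in sorted(replaced.items())),
        )
    return "".join(out)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a sanitized sequence as an int array over 0..19."""
    try:
        return np.array([AA_INDEX[ch] for ch in sequence], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded by sanitization
        raise ValueError(f"non-canonical residue {exc} in sequence") from exc


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 residue substitution scoring matrix.

    ``scores[i, j]`` is the score for substituting ``AMINO_ACIDS[i]`` with
    ``AMINO_ACIDS[j]``; a *column* is one residue's score vector against all
    twenty residues.
    """

    name: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (20, 20):
            raise ValueError(f"substitution matrix must be 20x20, got {s.shape}")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def column(self, residue: str) -> np.ndarray:
        """Score vector of ``residue`` against the full alphabet."""
        return self.scores[:, AA_INDEX[residue]].copy()


_BLOSUM62: SubstitutionMatrix | None = None


def blosum62() -> SubstitutionMatrix:
    """The published BLOSUM62 matrix restricted to the canonical alphabet."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        raw = substitution_matrices.load("BLOSUM62")
        scores = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                scores[i, j] = raw[a, b]
        _BLOSUM62 = SubstitutionMatrix(name="BLOSUM62", scores=scores)
    return _BLOSUM62
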