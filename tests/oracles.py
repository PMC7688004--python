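"""Independent brute-force oracles used to validate the kernel implementations.

These deliberately share no code with the package's dynamic-programming /
closed-form kernels: alignments are enumerated explicitly and the mismatch
kernel sums over the whole k-mer space.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from seqaffinity.alphabet import AMINO_ACIDS, AA_INDEX, blosum62

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def gap_cost(length: int) -> float:
    """Affine gap: the first gapped position pays open, the rest extend."""
    return 0.0 if length == 0 else GAP_OPEN + (length - 1) * GAP_EXTEND


def alignment_scores(a: str, b: str):
    """Scores of every (non-empty) gapped local alignment of a and b.

    A local alignment is an order-preserving matching of positions; interior
    gaps in either sequence are charged with the affine cost, flanks are free.
    """
    subs = blosum62()
    for t in range(1, min(len(a), len(b)) + 1):
        for rows in itertools.combinations(range(len(a)), t):
            for cols in itertools.combinations(range(len(b)), t):
                score = sum(subs.score(a[i], b[j]) for i, j in zip(rows, cols))
                for x in range(t - 1):
                    score -= gap_cost(rows[x + 1] - rows[x] - 1)
                    score -= gap_cost(cols[x + 1] - cols[x] - 1)
                yield score


def sw_oracle(a: str, b: str) -> float:
    """Best local alignment score; the empty alignment scores 0."""
    return max([0.0, *alignment_scores(a, b)])


def la_oracle(a: str, b: str, beta: float = 0.1) -> float:
    """Sum of exp(beta * score) over all alignments, empty one included."""
    return 1.0 + sum(math.exp(beta * s) for s in alignment_scores(a, b))


def mismatch_oracle(a: str, b: str, k: int, m: int) -> float:
    """sum_u N_a(u) * N_b(u) over all 20^k k-mers u (vectorized)."""

    def kmer_matrix(s: str) -> np.ndarray:
        idx = np.array([AA_INDEX[c] for c in s])
        return np.array([idx[i : i + k] for i in range(len(s) - k + 1)])

    ka, kb = kmer_matrix(a), kmer_matrix(b)
    universe = np.array(list(itertools.product(range(20), repeat=k)))
    na = ((universe[:, None, :] != ka[None, :, :]).sum(axis=2) <= m).sum(axis=1)
    nb = ((universe[:, None, :] != kb[None, :, :]).sum(axis=2) <= m).sum(axis=1)
    return float(na @ nb)


def spectrum_oracle(a: str, b: str, k: int) -> float:
    """Exact-k-mer spectrum kernel via explicit counting."""
    from collections import Counter

    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    return float(sum(ca[u] * cb[u] for u in ca))


def random_sequence(rng, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
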