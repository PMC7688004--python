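"""Chain-level string kernels: Smith-Waterman, local-alignment, and mismatch.

All three kernels score the similarity of two protein sequences:

* ``sw_kernel`` — the optimal affine-gap Smith-Waterman local-alignment score
  (BLOSUM62, gap open 11, extend 1 by default; a gap of length L costs
  ``open + (L-1)*extend``).  The empty alignment scores 0, so the kernel is
  non-negative.  Being a max of alignment scores it need not be positive
  semidefinite, hence :func:`psd_correct`.
* ``la_kernel`` — the local-alignment kernel: the sum of ``exp(beta * score)``
  over *all* local alignments, including the empty one (contributing
  ``exp(0) = 1``).  As ``beta`` grows, ``(1/beta) * log k_LA`` approaches the
  Smith-Waterman score.  The recursion is evaluated with running rescaling so
  arbitrarily large exponents are handled; the linear-space value raises a
  numeric error only if the final kernel value itself exceeds the float range
  (use :func:`la_kernel_log` in that regime).
* ``mismatch_kernel`` — the (k, m)-mismatch kernel: the inner product of
  k-mer neighbourhood-count profiles, ``sum_u N_a(u) * N_b(u)`` over the
  ``20^k`` k-mer space, where ``N_x(u)`` counts positions of ``x`` whose k-mer
  lies within Hamming distance ``m`` of ``u``.  It is evaluated without ever
  materializing the ``20^k`` space: the number of ``u`` simultaneously within
  distance ``m`` of two k-mers depends only on their Hamming distance ``d``,
  so the kernel is the sum of a precomputed per-distance statistic over all
  instance pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .alphabet import AMINO_ACIDS, SubstitutionMatrix, blosum62, encode_sequence
from .io import ProteinChain

_LOG_FLOAT_MAX = math.log(np.finfo(float).max)


def _as_string(seq) -> str:
    if isinstance(seq, ProteinChain):
        return seq.sequence
    return str(seq)


@dataclass(frozen=True, eq=False)
class AlignmentParams:
    """Scoring parameters shared by the alignment kernels.

    ``beta`` is the local-alignment kernel's sensitivity; larger values weight
    the optimal alignment more heavily.
    """

    substitution: SubstitutionMatrix = field(default_factory=blosum62)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    beta: float = 0.1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class MismatchParams:
    """(k, m)-mismatch kernel parameters; defaults k=5, m=3."""

    k: int = 5
    m: int = 3

    def __post_init__(self) -> None:
        # k down to 1 is permitted (k=1, m=0 reduces to the composition
        # dot-product); values above 9 blow up the neighbourhood size.
        if not 1 <= self.k <= 9:
            raise ValueError(f"k must be in 1..9, got {self.k}")
        if not 0 <= self.m <= 5 or self.m >= self.k:
            raise ValueError(f"m must satisfy 0 <= m <= 5 and m < k, got m={self.m}, k={self.k}")


# ---------------------------------------------------------------------------
# Smith-Waterman kernel

@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams):
    from Bio.Align import PairwiseAligner, substitution_matrices

    arr = substitution_matrices.Array(alphabet=AMINO_ACIDS, dims=2)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            arr[a, b] = params.substitution.scores[i, j]
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=arr,
        open_gap_score=-params.gap_open,
        extend_gap_score=-params.gap_extend,
    )
    return aligner


def sw_kernel(a, b, params: AlignmentParams | None = None) -> float:
    """Optimal local-alignment score of two sequences (non-negative)."""
    params = params or AlignmentParams()
    sa, sb = _as_string(a), _as_string(b)
    if not sa or not sb:
        raise ValueError("sw_kernel requires non-empty sequences")
    return float(max(0.0, _aligner(params).score(sa, sb)))


# ---------------------------------------------------------------------------
# Local-alignment kernel

def _la_log(sa: str, sb: str, params: AlignmentParams) -> float:
    """log of the LA kernel via the five-state recursion with rescaling.

    States per cell: M ends with an aligned pair; X/Y end with a gap in one
    sequence (Y may follow X but not vice versa, so each alignment is counted
    once); X2/Y2 accumulate terminated alignments.  The constant term for
    starting a fresh alignment is carried through the running rescale.
    """
    ea, eb = encode_sequence(sa), encode_sequence(sb)
    n, m = ea.size, eb.size
    beta = params.beta
    with np.errstate(over="raise"):
        expo = beta * params.substitution.scores[np.ix_(ea, eb)]
        if expo.max() > _LOG_FLOAT_MAX - 10:
            raise FloatingPointError("beta * substitution score overflows a float")
        S = np.exp(expo)  # (n, m)
    gd = math.exp(-beta * params.gap_open)
    ge = math.exp(-beta * params.gap_extend)
    # rescale before a row update can overflow: one step multiplies by at most
    # max(S) and sums O(m) terms
    rescale_threshold = 1e280 / (max(float(S.max()), 1.0) * max(m, 1))

    M = np.zeros(m + 1)
    X = np.zeros(m + 1)
    Y = np.zeros(m + 1)
    X2 = np.zeros(m + 1)
    Y2 = np.zeros(m + 1)
    log_scale = 0.0
    fresh = 1.0  # exp(-log_scale): weight of starting a new alignment
    for i in range(1, n + 1):
        Mp, Xp, Yp, X2p, Y2p = M, X, Y, X2, Y2
        srow = S[i - 1]
        M = np.empty(m + 1)
        M[0] = 0.0
        M[1:] = srow * (fresh + Xp[:-1] + Yp[:-1] + Mp[:-1])
        X = np.empty(m + 1)
        X[0] = 0.0
        X[1:] = gd * Mp[1:] + ge * Xp[1:]
        Y = np.empty(m + 1)
        Y[0] = 0.0
        Y[1:] = lfilter([1.0], [1.0, -ge], gd * (M[:-1] + X[:-1]))
        X2 = np.empty(m + 1)
        X2[0] = 0.0
        X2[1:] = Mp[1:] + X2p[1:]
        Y2 = np.empty(m + 1)
        Y2[0] = 0.0
        Y2[1:] = np.cumsum(M[:-1] + X2[:-1])

        peak = max(M.max(), X.max(), Y.max(), X2.max(), Y2.max())
        if peak > rescale_threshold:
            M /= peak; X /= peak; Y /= peak; X2 /= peak; Y2 /= peak
            log_scale += math.log(peak)
            fresh = math.exp(-log_scale) if log_scale < 745.0 else 0.0
    total = M[m] + X2[m] + Y2[m]
    if total <= 0.0:
        return 0.0  # only the empty alignment contributes
    return float(np.logaddexp(0.0, log_scale + math.log(total)))


def la_kernel(a, b, params: AlignmentParams | None = None) -> float:
    """Local-alignment kernel value (>= 1; includes the empty alignment)."""
    params = params or AlignmentParams()
    sa, sb = _as_string(a), _as_string(b)
    if not sa or not sb:
        raise ValueError("la_kernel requires non-empty sequences")
    log_k = _la_log(sa, sb, params)
    if log_k > _LOG_FLOAT_MAX:
        raise OverflowError(
            f"LA kernel value exp({log_k:.1f}) exceeds the float range; "
            "use la_kernel_log for the log value"
        )
    return float(math.exp(log_k))


def la_kernel_log(a, b, params: AlignmentParams | None = None) -> float:
    """Natural log of the local-alignment kernel (always representable)."""
    params = params or AlignmentParams()
    sa, sb = _as_string(a), _as_string(b)
    if not sa or not sb:
        raise ValueError("la_kernel_log requires non-empty sequences")
    return _la_log(sa, sb, params)


# ---------------------------------------------------------------------------
# Mismatch kernel

@lru_cache(maxsize=64)
def _pair_statistic(k: int, m: int, alphabet_size: int = 20) -> tuple[float, ...]:
    """f[d] = #{u : dist(u, x) <= m and dist(u, y) <= m} for k-mers x, y at
    Hamming distance d.

    At the k-d agreeing positions, u either matches (0/0 mismatch cost) or
    differs from both (1/1; ``alphabet-1`` choices).  At each of the d
    disagreeing positions u matches x (0/1), matches y (1/0) or neither (1/1;
    ``alphabet-2`` choices).
    """
    other_both = alphabet_size - 1
    other_neither = alphabet_size - 2
    f = []
    for d in range(k + 1):
        total = 0
        for j in range(k - d + 1):  # agreeing positions where u differs
            base = math.comb(k - d, j) * other_both**j
            inner = 0
            for x in range(d + 1):  # u matches the first k-mer
                for y in range(d - x + 1):  # u matches the second k-mer
                    z = d - x - y  # u matches neither
                    if j + y + z <= m and j + x + z <= m:
                        inner += (
                            math.factorial(d)
                            // (math.factorial(x) * math.factorial(y) * math.factorial(z))
                            * other_neither**z
                        )
            total += base * inner
        f.append(float(total))
    return tuple(f)


def mismatch_kernel(a, b, params: MismatchParams | None = None) -> float:
    """(k, m)-mismatch kernel between two sequences."""
    params = params or MismatchParams()
    sa, sb = _as_string(a), _as_string(b)
    k = params.k
    if len(sa) < k or len(sb) < k:
        raise ValueError(
            f"mismatch kernel needs sequences of length >= k={k}; "
            f"got {len(sa)} and {len(sb)}"
        )
    ka = np.lib.stride_tricks.sliding_window_view(encode_sequence(sa), k)
    kb = np.lib.stride_tricks.sliding_window_view(encode_sequence(sb), k)
    dist = (ka[:, None, :] != kb[None, :, :]).sum(axis=2)
    f = np.array(_pair_statistic(k, params.m))
    return float(f[dist].sum())


# ---------------------------------------------------------------------------
# Gram matrices and PSD correction

@dataclass(frozen=True, eq=False)
class GramMatrix:
    """Symmetric kernel evaluations over a list of items."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    kernel_name: str = "custom"
    psd_corrected: bool = False
    lambda_min_removed: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"Gram matrix shape {v.shape} does not match {n} ids")
        tol = 1e-9 * max(1.0, float(np.abs(v).max()) if v.size else 1.0)
        if not np.allclose(v, v.T, atol=tol, rtol=1e-9):
            raise ValueError("Gram matrix must be symmetric")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", v)

    def submatrix(self, indices) -> "GramMatrix":
        idx = np.asarray(indices)
        return replace(
            self,
            ids=tuple(np.asarray(self.ids)[idx]),
            values=self.values[np.ix_(idx, idx)],
        )


def gram(items, kernel, ids=None, kernel_name: str = "custom", normalize: bool = False) -> GramMatrix:
    """Pairwise kernel matrix, each unordered pair evaluated once.

    ``normalize=True`` applies cosine normalization
    ``k(a,b)/sqrt(k(a,a) k(b,b))`` (off by default).
    """
    items = list(items)
    if not items:
        raise ValueError("gram requires at least one item")
    if ids is None:
        ids = [getattr(it, "id", str(i)) for i, it in enumerate(items)]
    n = len(items)
    values = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            try:
                values[i, j] = values[j, i] = kernel(items[i], items[j])
            except Exception as exc:
                raise RuntimeError(
                    f"kernel {kernel_name!r} failed for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
    if normalize:
        diag = np.sqrt(np.diag(values))
        if np.any(diag <= 0):
            raise ValueError("cosine normalization requires positive self-kernel values")
        values = values / np.outer(diag, diag)
        kernel_name = f"{kernel_name}_cosine"
    return GramMatrix(ids=tuple(ids), values=values, kernel_name=kernel_name)


def psd_correct(g: GramMatrix | np.ndarray) -> GramMatrix | np.ndarray:
    """Shift the diagonal by the most negative eigenvalue, if any.

    Returns the input unchanged when it is already positive semidefinite.
    Idempotent: a corrected matrix has smallest eigenvalue ~0 and passes
    through untouched (up to floating-point round-off).
    """
    if isinstance(g, GramMatrix):
        values = g.values
    else:
        values = np.asarray(g, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("psd_correct requires a square matrix")
        tol = 1e-9 * max(1.0, float(np.abs(values).max()) if values.size else 1.0)
        if not np.allclose(values, values.T, atol=tol, rtol=1e-9):
            raise ValueError("psd_correct requires a symmetric matrix")
    lam_min = float(np.linalg.eigvalsh((values + values.T) / 2.0).min())
    if lam_min >= 0:
        return g
    corrected = values - lam_min * np.eye(values.shape[0])
    if isinstance(g, GramMatrix):
        return replace(g, values=corrected, psd_corrected=True, lambda_min_removed=lam_min)
    return corrected


# ---------------------------------------------------------------------------
# Text serialization

def write_gram(g: GramMatrix, path: str | Path) -> None:
    """Tab-delimited Gram matrix with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# kernel_name\t{g.kernel_name}\n")
        fh.write(f"# psd_corrected\t{g.psd_corrected}\n")
        fh.write(f"# lambda_min_removed\t{g.lambda_min_removed!r}\n")
        fh.write("id\t" + "\t".join(g.ids) + "\n")
        for i, row_id in enumerate(g.ids):
            fh.write(row_id + "\t" + "\t".join(repr(float(v)) for v in g.values[i]) + "\n")


def read_gram(path: str | Path) -> GramMatrix:
    meta = {"kernel_name": "custom", "psd_corrected": "False", "lambda_min_removed": "0.0"}
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = value.strip()
            elif line.startswith("id\t"):
                continue
            elif line:
                parts = line.split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
    return GramMatrix(
        ids=tuple(ids),
        values=np.array(rows),
        kernel_name=meta["kernel_name"],
        psd_corrected=meta["psd_corrected"] == "True",
        lambda_min_removed=float(meta["lambda_min_removed"]),
    )
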