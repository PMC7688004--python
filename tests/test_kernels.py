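import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import la_oracle, mismatch_oracle, spectrum_oracle, sw_oracle

from seqaffinity import (
    AMINO_ACIDS,
    AlignmentParams,
    GramMatrix,
    MismatchParams,
    gram,
    la_kernel,
    la_kernel_log,
    mismatch_kernel,
    psd_correct,
    read_gram,
    sw_kernel,
    write_gram,
)

seqs = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=6)
longer_seqs = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=12)


class TestSmithWaterman:
    def test_identical_tryptophan_pair(self):
        # two W-W aligned pairs at BLOSUM62(W, W) = 11 each
        assert sw_kernel("WW", "WW") == 22.0

    def test_empty_alignment_floors_at_zero(self):
        assert sw_kernel("A", "D") == 0.0  # BLOSUM62(A, D) = -2

    def test_gap_cost_convention(self):
        # ACDEFG vs ACFG: match ACFG with a 2-gap costing 11 + 1
        assert sw_kernel("ACDEFG", "ACFG") == (4 + 9 + 6 + 6) - 12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_symmetry_and_nonnegativity(self, a, b):
        assert sw_kernel(a, b) == sw_kernel(b, a) >= 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_matches_enumeration_oracle(self, a, b):
        assert sw_kernel(a, b) == pytest.approx(sw_oracle(a, b), abs=1e-9)


class TestLocalAlignmentKernel:
    def test_single_alanine_pair(self):
        # alignments: empty, plus A-A scoring BLOSUM62(A, A) = 4
        assert la_kernel("A", "A") == pytest.approx(1 + math.exp(0.4), rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_matches_enumeration_oracle(self, a, b):
        expected = la_oracle(a, b, beta=0.1)
        assert la_kernel(a, b) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_at_least_one_from_empty_alignment(self, a, b):
        assert la_kernel(a, b) >= 1.0

    def test_monotone_in_beta_for_positive_best_score(self):
        a, b = "MKWVT", "MKWVT"
        values = [la_kernel(a, b, AlignmentParams(beta=beta)) for beta in (0.05, 0.1, 0.5, 1.0)]
        assert np.all(np.diff(values) > 0)

    def test_log_variant_consistent_with_linear(self):
        a, b = "MKWVTF", "MKYVT"
        assert la_kernel_log(a, b) == pytest.approx(math.log(la_kernel(a, b)), rel=1e-12)

    def test_log_variant_handles_huge_exponents(self):
        params = AlignmentParams(beta=20.0)
        seq = "MKWVTFISLL" * 4  # self-score far beyond linear float range
        log_k = la_kernel_log(seq, seq, params)
        assert log_k > 710  # not representable linearly
        with pytest.raises(OverflowError):
            la_kernel(seq, seq, params)

    def test_approaches_smith_waterman_for_large_beta(self):
        params = AlignmentParams(beta=20.0)
        for a, b in [("MKWVT", "MKWVT"), ("ACDEFG", "ACFG"), ("WWW", "WW")]:
            assert la_kernel_log(a, b, params) / 20.0 == pytest.approx(
                sw_kernel(a, b), abs=0.5
            )


class TestMismatchKernel:
    def test_reduces_to_composition_dot_product(self):
        # k=1, m=0: A*A + C*C = 2
        assert mismatch_kernel("AC", "CA", MismatchParams(k=1, m=0)) == 2.0

    def test_shared_neighbourhood_count_k2_m1(self):
        # brute-force over all 400 2-mers: 20 k-mers lie within Hamming
        # distance 1 of both AA and AC
        assert mismatch_kernel("AA", "AC", MismatchParams(k=2, m=1)) == 20.0
        assert mismatch_oracle("AA", "AC", 2, 1) == 20.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=longer_seqs, b=longer_seqs)
    def test_m0_equals_spectrum_kernel(self, a, b):
        params = MismatchParams(k=3, m=0)
        assert mismatch_kernel(a, b, params) == spectrum_oracle(a, b, 3)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=8),
        b=st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=8),
        k=st.integers(min_value=1, max_value=3),
        m=st.integers(min_value=0, max_value=1),
    )
    def test_matches_bruteforce_oracle(self, a, b, k, m):
        if m >= k:
            m = k - 1
        params = MismatchParams(k=k, m=m)
        assert mismatch_kernel(a, b, params) == mismatch_oracle(a, b, k, m)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="length >= k"):
            mismatch_kernel("ACD", "AC", MismatchParams(k=3, m=1))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MismatchParams(k=0, m=0)
        with pytest.raises(ValueError):
            MismatchParams(k=3, m=3)
        with pytest.raises(ValueError):
            MismatchParams(k=10, m=2)


class TestGram:
    def test_single_item(self):
        g = gram(["WW"], sw_kernel, ids=["a"])
        assert g.values.shape == (1, 1) and g.values[0, 0] == 22.0

    def test_permutation_consistency(self):
        items = ["WW", "MKV", "ACDE"]
        g1 = gram(items, sw_kernel, ids=["a", "b", "c"])
        g2 = gram(items[::-1], sw_kernel, ids=["c", "b", "a"])
        assert np.allclose(g1.values, g2.values[::-1, ::-1])

    def test_entries_match_direct_kernel_calls(self, rng):
        from oracles import random_sequence

        items = [random_sequence(rng, 3, 8) for _ in range(4)]
        g = gram(items, sw_kernel)
        for i, j in [(0, 3), (1, 2), (2, 0)]:
            assert g.values[i, j] == sw_kernel(items[i], items[j])

    def test_kernel_failure_names_the_pair(self):
        def broken(a, b):
            if a != b:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match=r"\('x', 'y'\)"):
            gram(["AA", "CC"], broken, ids=["x", "y"])

    def test_cosine_normalization_gives_unit_diagonal(self):
        g = gram(["WWW", "MKV", "WWMKV"], sw_kernel, normalize=True)
        assert np.allclose(np.diag(g.values), 1.0)

    def test_round_trip_through_text(self, tmp_path):
        g = gram(["WW", "MKV"], sw_kernel, ids=["a", "b"], kernel_name="sw")
        path = tmp_path / "g.tsv"
        write_gram(g, path)
        back = read_gram(path)
        assert back.ids == g.ids and back.kernel_name == "sw"
        assert np.array_equal(back.values, g.values)


class TestPsdCorrection:
    def test_two_by_two_hand_eigendecomposition(self):
        # [[0,1],[1,0]] has eigenvalues +-1; shifting by +1 gives [[1,1],[1,1]]
        corrected = psd_correct(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(corrected, np.ones((2, 2)))
        assert np.linalg.eigvalsh(corrected).min() >= -1e-8

    def test_already_psd_returned_unchanged(self):
        g = GramMatrix(ids=("a", "b"), values=np.eye(2), kernel_name="k")
        assert psd_correct(g) is g
        assert g.psd_corrected is False

    def test_gram_metadata_records_the_shift(self):
        g = GramMatrix(
            ids=("a", "b"), values=np.array([[0.0, 1.0], [1.0, 0.0]]), kernel_name="k"
        )
        corrected = psd_correct(g)
        assert corrected.psd_corrected is True
        assert corrected.lambda_min_removed == pytest.approx(-1.0)

    def test_random_symmetric_matrices_become_psd_and_idempotent(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            a = rng.normal(size=(n, n))
            sym = (a + a.T) / 2
            corrected = psd_correct(sym)
            assert np.linalg.eigvalsh(corrected).min() >= -1e-8
            twice = psd_correct(corrected)
            twice = twice if isinstance(twice, np.ndarray) else twice.values
            assert np.allclose(twice, corrected, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            psd_correct(np.array([[0.0, 2.0], [1.0, 0.0]]))

    def test_gram_matrix_symmetry_invariant(self):
        with pytest.raises(ValueError, match="symmetric"):
            GramMatrix(ids=("a", "b"), values=np.array([[0.0, 2.0], [1.0, 0.0]]))
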