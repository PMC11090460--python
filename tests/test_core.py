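"""Core factorization: eigendecompositions, Hadamard/Kronecker oracles, tensor-EVD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tensorevd import (
    DesignError,
    InvalidKernelError,
    Kernel,
    LabelResolutionError,
    NotPositiveSemidefiniteError,
    eigen_sym,
    hadamard_kernel,
    kronecker_evd,
    reconstruct,
    tensor_evd,
    truncate_evd,
)
from tests.conftest import full_crossing, make_psd_kernel, random_design


def rel_fro(A, B):
    return np.linalg.norm(A - B, "fro") / max(np.linalg.norm(B, "fro"), 1e-300)


class TestKernel:
    def test_rejects_nonsquare(self):
        with pytest.raises(InvalidKernelError, match="square"):
            Kernel(values=np.zeros((2, 3)), labels=np.array(["a", "b"]))

    def test_rejects_asymmetric(self):
        with pytest.raises(InvalidKernelError, match="asymmetric"):
            Kernel(values=np.array([[1.0, 0.3], [0.0, 1.0]]), labels=np.array(["a", "b"]))

    def test_rejects_duplicate_or_missing_labels(self):
        with pytest.raises(InvalidKernelError, match="unique"):
            Kernel(values=np.eye(2), labels=np.array(["a", "a"]))
        with pytest.raises(InvalidKernelError, match="labels"):
            Kernel(values=np.eye(2), labels=np.array(["a"]))

    def test_tolerates_roundoff_asymmetry(self):
        V = np.array([[1.0, 1e-13], [0.0, 1.0]])
        K = Kernel(values=V @ np.diag([2.0, 1.0]) @ V.T, labels=np.array(["a", "b"]))
        assert np.allclose(K.values, K.values.T)


class TestEigenSym:
    def test_hand_computed_2x2(self):
        # characteristic polynomial x^2 - 4x + 3 = (x-3)(x-1)
        K = Kernel(values=np.array([[2.0, 1.0], [1.0, 2.0]]), labels=np.array(["a", "b"]))
        ev = eigen_sym(K)
        assert np.allclose(ev.values, [3.0, 1.0], atol=1e-12)
        assert ev.total_variance == pytest.approx(4.0)

    def test_identity_and_diagonal(self):
        ev = eigen_sym(Kernel(np.eye(3), np.array(["a", "b", "c"])))
        assert np.allclose(ev.values, 1.0)
        ev2 = eigen_sym(Kernel(np.diag([4.0, 1.0]), np.array(["a", "b"])))
        assert np.allclose(ev2.values, [4.0, 1.0])
        assert np.allclose(np.abs(ev2.vectors), np.eye(2), atol=1e-12)

    def test_orthonormal_and_reconstructs(self):
        K = make_psd_kernel(12, seed=7)
        ev = eigen_sym(K)
        assert np.allclose(ev.vectors.T @ ev.vectors, np.eye(12), atol=1e-8)
        assert rel_fro(reconstruct(ev), K.values) < 1e-8
        assert np.all(np.diff(ev.values) <= 1e-12)

    def test_clamps_tiny_negatives_but_rejects_indefinite(self):
        # rank-deficient kernel: roundoff-scale negative eigenvalues get clamped
        K = make_psd_kernel(10, seed=3, rank=4)
        ev = eigen_sym(K)
        assert np.all(ev.values >= 0.0)
        with pytest.raises(NotPositiveSemidefiniteError):
            eigen_sym(Kernel(np.diag([1.0, -0.5]), np.array(["a", "b"])))

    def test_sign_convention_deterministic(self):
        K = make_psd_kernel(8, seed=11)
        V = eigen_sym(K).vectors
        peak = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])]
        assert np.all(peak > 0)


class TestHadamardKernel:
    def test_toy_example(self, toy_pair):
        K = hadamard_kernel(*toy_pair)
        expected = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        assert np.allclose(K.values, expected)

    def test_full_crossing_is_kronecker(self):
        K1 = make_psd_kernel(2, seed=1)
        K2 = make_psd_kernel(2, seed=2, prefix="M")
        id1, id2 = full_crossing(K1.labels, K2.labels)
        K = hadamard_kernel(K1, K2, id1, id2)
        assert np.allclose(K.values, np.kron(K1.values, K2.values), atol=1e-12)

    def test_replicated_result_is_psd(self):
        K1 = make_psd_kernel(3, seed=5)
        K2 = make_psd_kernel(2, seed=6, prefix="M")
        id1, id2 = random_design(K1.labels, K2.labels, 7, seed=9)
        K = hadamard_kernel(K1, K2, id1, id2)
        w = np.linalg.eigvalsh(K.values)
        assert w[0] >= -1e-8 * max(w[-1], 1e-300)

    def test_errors_name_the_problem(self, toy_pair):
        K1, K2, ID1, ID2 = toy_pair
        with pytest.raises(DesignError, match="unequal"):
            hadamard_kernel(K1, K2, ID1, ID2[:2])
        with pytest.raises(LabelResolutionError, match="'C'"):
            hadamard_kernel(K1, K2, np.array(["A", "C", "B"]), ID2)


class TestKroneckerEVD:
    def test_diagonal_products_sorted(self):
        K1 = Kernel(np.diag([2.0, 1.0]), np.array(["a", "b"]))
        K2 = Kernel(np.diag([3.0, 1.0]), np.array(["x", "y"]))
        ev = kronecker_evd(K1, K2)
        assert np.allclose(ev.values, [6.0, 3.0, 2.0, 1.0])
        assert ev.total_variance == pytest.approx(12.0)

    def test_identity_factors(self):
        ev = kronecker_evd(
            Kernel(np.eye(2), np.array(["a", "b"])),
            Kernel(np.eye(3), np.array(["x", "y", "z"])),
        )
        assert np.allclose(ev.values, 1.0)
        assert ev.n_vectors == 6

    def test_matches_explicit_kronecker_oracle(self):
        K1 = make_psd_kernel(3, seed=21)
        K2 = make_psd_kernel(4, seed=22, prefix="M")
        ev = kronecker_evd(K1, K2)
        Kk = np.kron(K1.values, K2.values)
        w = np.linalg.eigvalsh(Kk)[::-1]
        assert np.allclose(ev.values, np.clip(w, 0, None), atol=1e-8)
        assert np.allclose(ev.vectors.T @ ev.vectors, np.eye(12), atol=1e-8)
        assert rel_fro(reconstruct(ev), Kk) < 1e-8


class TestTensorEVD:
    def test_identity_full_crossing(self):
        I2 = Kernel(np.eye(2), np.array(["a", "b"]))
        J2 = Kernel(np.eye(2), np.array(["x", "y"]))
        id1, id2 = full_crossing(I2.labels, J2.labels)
        ev = tensor_evd(I2, J2, id1, id2, alpha=1.0)
        assert ev.n_vectors == 4
        assert np.allclose(ev.values, 1.0)
        assert ev.alpha_achieved == pytest.approx(1.0)
        assert np.allclose(ev.vectors.T @ ev.vectors, np.eye(4), atol=1e-10)

    def test_toy_example_reproduces_hadamard(self, toy_pair):
        K1, K2, ID1, ID2 = toy_pair
        ev = tensor_evd(K1, K2, ID1, ID2, alpha=1.0)
        assert ev.values.sum() == pytest.approx(3.0)  # trace of the 3x3 Hadamard matrix
        K = hadamard_kernel(K1, K2, ID1, ID2)
        assert rel_fro(reconstruct(ev), K.values) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_unbalanced_exactness_at_alpha_one(self, seed):
        K1 = make_psd_kernel(6, seed=seed)
        K2 = make_psd_kernel(4, seed=seed + 100, prefix="M")
        id1, id2 = random_design(K1.labels, K2.labels, 50, seed=seed + 200)
        ev = tensor_evd(K1, K2, id1, id2, alpha=1.0)
        K = hadamard_kernel(K1, K2, id1, id2)
        assert rel_fro(reconstruct(ev), K.values) < 1e-8
        tr = float(np.trace(K.values))
        assert abs(ev.values.sum() - tr) <= 1e-10 * tr

    def test_unit_norms_and_descending_values(self):
        K1 = make_psd_kernel(5, seed=31)
        K2 = make_psd_kernel(3, seed=32, prefix="M")
        id1, id2 = random_design(K1.labels, K2.labels, 40, seed=33)
        ev = tensor_evd(K1, K2, id1, id2, alpha=0.95)
        norms = np.linalg.norm(ev.vectors, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)
        assert np.all(np.diff(ev.values) <= 1e-12)
        assert ev.alpha_achieved >= 0.95

    def test_monotone_approximation_in_alpha(self):
        K1 = make_psd_kernel(20, seed=41)
        K2 = make_psd_kernel(5, seed=42, prefix="M")
        id1, id2 = random_design(K1.labels, K2.labels, 60, seed=43)
        K = hadamard_kernel(K1, K2, id1, id2).values
        dists = []
        for a in [0.5, 0.7, 0.9, 0.95, 0.98, 1.0]:
            ev = tensor_evd(K1, K2, id1, id2, alpha=a)
            # the >= contract applies to truncated runs; alpha=1 is exact up to roundoff
            assert ev.alpha_achieved >= (a if a < 1.0 else 1.0 - 1e-10)
            dists.append(np.linalg.norm(reconstruct(ev) - K, "fro"))
        assert all(d1 >= d2 - 1e-9 for d1, d2 in zip(dists, dists[1:]))
        assert dists[-1] < 1e-8 * np.linalg.norm(K, "fro")

    def test_balanced_matches_kronecker_rank(self):
        K1 = make_psd_kernel(5, seed=51, rank=2)
        K2 = make_psd_kernel(4, seed=52, rank=3, prefix="M")
        id1, id2 = full_crossing(K1.labels, K2.labels)
        ev = tensor_evd(K1, K2, id1, id2, alpha=1.0)
        assert ev.n_vectors == 2 * 3
        kr = kronecker_evd(K1, K2)
        pos = kr.values > 0
        assert np.allclose(np.sort(ev.values), np.sort(kr.values[pos]), atol=1e-8)

    def test_zero_norm_candidates_dropped(self):
        # sampling only label 'a' of an identity kernel zeroes the e_b eigenvector
        I2 = Kernel(np.eye(2), np.array(["a", "b"]))
        one = Kernel(np.ones((1, 1)), np.array(["e"]))
        ev = tensor_evd(I2, one, np.array(["a", "a"]), np.array(["e", "e"]), alpha=1.0)
        assert ev.n_vectors == 1
        assert ev.values.sum() == pytest.approx(2.0)  # trace still fully captured

    def test_permutation_equivariance(self):
        K1 = make_psd_kernel(4, seed=61)
        K2 = make_psd_kernel(3, seed=62, prefix="M")
        id1, id2 = random_design(K1.labels, K2.labels, 25, seed=63)
        ev = tensor_evd(K1, K2, id1, id2, alpha=0.9)
        perm = np.random.default_rng(64).permutation(25)
        evp = tensor_evd(K1, K2, id1[perm], id2[perm], alpha=0.9)
        assert np.allclose(evp.vectors, ev.vectors[perm], atol=1e-12)
        assert np.allclose(evp.values, ev.values)

    def test_raw_value_flag_keeps_kronecker_eigenvalues(self, toy_pair):
        K1, K2, ID1, ID2 = toy_pair
        ev_raw = tensor_evd(K1, K2, ID1, ID2, alpha=1.0, rescale=False, order_by="raw")
        # raw values are the Kronecker eigenvalues of K1 (x) K2, here (1.5, 0.5)
        assert np.allclose(ev_raw.values, [1.5, 0.5])
        ev = tensor_evd(K1, K2, ID1, ID2, alpha=1.0)
        assert not np.allclose(ev.values, ev_raw.values)

    def test_alpha_validation(self, toy_pair):
        K1, K2, ID1, ID2 = toy_pair
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="alpha"):
                tensor_evd(K1, K2, ID1, ID2, alpha=bad)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n1=st.integers(2, 7),
        n2=st.integers(2, 5),
        n=st.integers(5, 40),
    )
    def test_property_exact_reconstruction_any_design(self, seed, n1, n2, n):
        K1 = make_psd_kernel(n1, seed=seed)
        K2 = make_psd_kernel(n2, seed=seed + 1, prefix="M")
        id1, id2 = random_design(K1.labels, K2.labels, n, seed=seed + 2)
        ev = tensor_evd(K1, K2, id1, id2, alpha=1.0)
        K = hadamard_kernel(K1, K2, id1, id2)
        assert rel_fro(reconstruct(ev), K.values) < 1e-8


class TestReconstructAndTruncate:
    def test_single_vector(self):
        from tensorevd import EVDResult

        ev = EVDResult(vectors=np.array([[1.0], [0.0]]), values=np.array([2.0]), total_variance=2.0)
        assert np.allclose(reconstruct(ev), [[2.0, 0.0], [0.0, 0.0]])

    def test_empty_basis_gives_zero_matrix(self):
        from tensorevd import EVDResult

        ev = EVDResult(vectors=np.zeros((3, 0)), values=np.zeros(0), total_variance=1.0)
        assert np.allclose(reconstruct(ev), np.zeros((3, 3)))

    def test_truncate_meets_target_fraction(self):
        K = make_psd_kernel(10, seed=71)
        full = eigen_sym(K)
        for a in (0.5, 0.9, 0.99):
            tr = truncate_evd(full, a)
            assert tr.alpha_achieved >= a
            assert tr.n_vectors <= full.n_vectors
        assert truncate_evd(full, 1.0).n_vectors == int(np.sum(full.values > 0))
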