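"""CPD-ALS and truncated HOSVD: recovery, bounds, and an independent oracle.

The oracle is Jennrich's direct (non-iterative) algorithm: for an
exactly low-rank tensor with linearly independent factors, two random
slice mixtures share eigenvectors equal to the mode-1 factor columns,
after which the remaining factors follow from rank-1 splits of the
projected unfolding.  It shares no code path with the ALS implementation.
"""

import numpy as np
import pytest

from speckleflow.decomposition import (
    CPDecomposition,
    core_from_factors,
    cpd_als,
    hosvd,
    load_decomposition,
    reconstruct_cpd,
    reconstruct_tucker,
    relative_error,
    save_decomposition,
)
from speckleflow.tensor_core import frobenius_norm, unfold

from conftest import rank_r_tensor, random_unit_columns


# ---------------------------------------------------------------- oracle

def jennrich_cpd(X, rank, seed=0):
    """Direct CPD of an exactly rank-`rank` tensor via simultaneous
    diagonalization of two random slice mixtures."""
    rng = np.random.default_rng(seed)
    Y1 = np.einsum("ijk,k->ij", X, rng.standard_normal(X.shape[2]))
    Y2 = np.einsum("ijk,k->ij", X, rng.standard_normal(X.shape[2]))
    eigvals, eigvecs = np.linalg.eig(Y1 @ np.linalg.pinv(Y2))
    keep = np.argsort(-np.abs(eigvals))[:rank]
    A = np.real(eigvecs[:, keep])
    A /= np.linalg.norm(A, axis=0)
    # rows of pinv(A) X(1) are kron(c_r, b_r); a rank-1 SVD splits them
    M = np.linalg.pinv(A) @ unfold(X, 1)
    J, K = X.shape[1], X.shape[2]
    B = np.empty((J, rank))
    C = np.empty((K, rank))
    lam = np.empty(rank)
    for r in range(rank):
        G = M[r].reshape(K, J)  # row-major over (k, j): k slow, j fast
        U, s, Vt = np.linalg.svd(G)
        lam[r] = s[0]
        C[:, r] = U[:, 0]
        B[:, r] = Vt[0]
    return lam, A, B, C


def align_components(ref_factors, factors):
    """Permute/sign-align `factors` (list of matrices) onto `ref_factors`
    by maximal absolute mode-1 column correlation; returns aligned copies
    and the permutation."""
    A_ref, A = ref_factors[0], factors[0]
    R = A.shape[1]
    corr = np.abs(A_ref.T @ A)
    perm = []
    used = set()
    for r in range(R):
        order = np.argsort(-corr[r])
        pick = next(c for c in order if c not in used)
        used.add(pick)
        perm.append(pick)
    aligned = [F[:, perm].copy() for F in factors]
    # joint sign flips per component: match each mode's sign to the reference
    for r in range(R):
        signs = [np.sign(ref[:, r] @ ali[:, r]) or 1.0
                 for ref, ali in zip(ref_factors, aligned)]
        if np.prod(signs) < 0:  # an odd flip would change the tensor; skip it
            signs[int(np.argmax([abs(s) for s in signs]))] *= -1
        for F, s in zip(aligned, signs):
            F[:, r] *= s
    return aligned, perm


# ------------------------------------------------------------------ CPD

class TestCpdAls:
    def test_exact_rank1_recovery(self, rng):
        X, (A, B, C) = rank_r_tensor(rng, (6, 5, 7), [2.0])
        d = cpd_als(X, rank=1, seed=0)
        assert d.final_objective < 1e-8
        assert d.weights[0] == pytest.approx(2.0, abs=1e-6)

    def test_rank3_weight_recovery(self, rng):
        X, _ = rank_r_tensor(rng, (10, 10, 10), [3.0, 2.0, 1.0])
        d = cpd_als(X, rank=3, seed=0)
        assert d.final_objective < 1e-6
        np.testing.assert_allclose(d.weights, [3.0, 2.0, 1.0], atol=1e-3)

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.standard_normal((6, 7, 8))
        d = cpd_als(X, rank=2, max_iter=60, seed=3)
        diffs = np.diff(d.objective_history)
        assert np.all(diffs <= 1e-12)

    def test_factor_columns_unit_norm_weights_sorted(self, rng):
        X, _ = rank_r_tensor(rng, (8, 8, 8), [5.0, 1.0, 0.5])
        d = cpd_als(X, rank=3, seed=1)
        for F in (d.factor_A, d.factor_B, d.factor_C):
            np.testing.assert_allclose(np.linalg.norm(F, axis=0), 1.0, atol=1e-10)
        assert np.all(np.diff(d.weights) <= 0)
        assert np.all(d.weights >= 0)

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((5, 6, 7))
        d1 = cpd_als(X, rank=2, max_iter=40, seed=9)
        d2 = cpd_als(X, rank=2, max_iter=40, seed=9)
        np.testing.assert_array_equal(d1.factor_C, d2.factor_C)
        np.testing.assert_array_equal(d1.weights, d2.weights)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.standard_normal((4, 4, 4))
        with pytest.raises(ValueError):
            cpd_als(X, rank=0)
        with pytest.raises(ValueError):
            cpd_als(np.zeros((3, 3, 3)), rank=1)
        Xbad = X.copy()
        Xbad[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            cpd_als(Xbad, rank=1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_jennrich_oracle(self, seed):
        """ALS factors match the independent direct algorithm to 1e-3."""
        rng = np.random.default_rng(100 + seed)
        X, truth = rank_r_tensor(rng, (6, 6, 6), [3.0, 2.0, 1.0])
        lam_j, *oracle = jennrich_cpd(X, rank=3, seed=seed)
        d = cpd_als(X, rank=3, seed=seed)
        als = [d.factor_A, d.factor_B, d.factor_C]
        aligned, perm = align_components(oracle, als)
        np.testing.assert_allclose(d.weights[perm], lam_j, atol=1e-3)
        for F_oracle, F_als in zip(oracle, aligned):
            np.testing.assert_allclose(
                np.abs(F_oracle), np.abs(F_als), atol=1e-3
            )


class TestReconstructCpd:
    def test_canonical_basis_rank1(self):
        e = np.zeros((3, 1))
        e[0, 0] = 1.0
        d = CPDecomposition(weights=np.array([1.0]), factor_A=e.copy(),
                            factor_B=e.copy(), factor_C=e.copy())
        X = reconstruct_cpd(d)
        expected = np.zeros((3, 3, 3))
        expected[0, 0, 0] = 1.0
        np.testing.assert_array_equal(X, expected)

    def test_full_rank_recovery_roundtrip(self, rng):
        X, _ = rank_r_tensor(rng, (5, 5, 5), [2.0, 1.0])
        d = cpd_als(X, rank=2, seed=0)
        assert relative_error(X, reconstruct_cpd(d)) < 1e-6

    def test_linearity_of_concatenated_components(self, rng):
        A = random_unit_columns(rng, 4, 2)
        B = random_unit_columns(rng, 5, 2)
        C = random_unit_columns(rng, 6, 2)
        lam = np.array([2.0, 0.5])
        full = CPDecomposition(weights=lam, factor_A=A, factor_B=B, factor_C=C)
        parts = [
            CPDecomposition(weights=lam[r:r + 1], factor_A=A[:, r:r + 1],
                            factor_B=B[:, r:r + 1], factor_C=C[:, r:r + 1])
            for r in range(2)
        ]
        np.testing.assert_allclose(
            reconstruct_cpd(full),
            reconstruct_cpd(parts[0]) + reconstruct_cpd(parts[1]),
            rtol=1e-12,
        )


# ---------------------------------------------------------------- Tucker

class TestHosvd:
    def test_full_rank_exact_reconstruction(self, rng):
        X = rng.standard_normal((6, 5, 4))
        T = hosvd(X, (6, 5, 4))
        assert relative_error(X, reconstruct_tucker(T)) < 1e-10

    def test_factor_orthonormality(self, rng):
        X = rng.standard_normal((8, 8, 8))
        T = hosvd(X, (4, 3, 2))
        for F in (T.factor_A, T.factor_B, T.factor_C):
            np.testing.assert_allclose(F.T @ F, np.eye(F.shape[1]), atol=1e-10)

    def test_truncation_respects_discarded_singular_value_bound(self, rng):
        X = rng.standard_normal((8, 8, 8))
        ranks = (4, 4, 4)
        T = hosvd(X, ranks)
        err_sq = frobenius_norm(X - reconstruct_tucker(T)) ** 2
        bound = sum(
            (np.linalg.svd(unfold(X, mode), compute_uv=False)[ranks[mode - 1]:] ** 2).sum()
            for mode in (1, 2, 3)
        )
        assert err_sq <= bound + 1e-10

    def test_error_monotone_in_rank(self, rng):
        X = rng.standard_normal((6, 6, 6))
        errs = [
            relative_error(X, reconstruct_tucker(hosvd(X, (r, 3, 3))))
            for r in range(1, 7)
        ]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_invalid_rank_rejected(self, rng):
        X = rng.standard_normal((4, 4, 4))
        with pytest.raises(ValueError):
            hosvd(X, (5, 2, 2))
        with pytest.raises(ValueError):
            hosvd(X, (0, 2, 2))


class TestCoreFromFactors:
    def test_identity_factors_return_input(self, rng):
        X = rng.standard_normal((4, 5, 6))
        G = core_from_factors(X, np.eye(4), np.eye(5), np.eye(6))
        np.testing.assert_allclose(G, X, rtol=1e-12)

    def test_construct_then_recover_core(self, rng):
        G0 = rng.standard_normal((3, 3, 3))
        factors = [np.linalg.qr(rng.standard_normal((n, 3)))[0] for n in (6, 7, 8)]
        from speckleflow.tensor_core import mode_n_product

        X = mode_n_product(mode_n_product(mode_n_product(G0, factors[0], 1),
                                          factors[1], 2), factors[2], 3)
        G = core_from_factors(X, *factors)
        np.testing.assert_allclose(G, G0, atol=1e-10)

    def test_core_norm_equals_projection_norm(self, rng):
        X = rng.standard_normal((6, 6, 6))
        T = hosvd(X, (3, 3, 3))
        np.testing.assert_allclose(
            frobenius_norm(T.core),
            frobenius_norm(reconstruct_tucker(T)),
            rtol=1e-10,
        )


class TestRelativeError:
    def test_trivial_values(self, rng):
        X = rng.standard_normal((3, 3, 3))
        assert relative_error(X, X) == 0.0
        assert relative_error(X, np.zeros_like(X)) == pytest.approx(1.0)
        assert relative_error(X, 2 * X) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))


def test_hdf5_roundtrip(tmp_path, rng):
    X, _ = rank_r_tensor(rng, (5, 5, 5), [2.0, 1.0])
    d = cpd_als(X, rank=2, seed=0)
    d.subject_id, d.site = "s1", "anastomosis"
    path = tmp_path / "cpd.h5"
    save_decomposition(d, path)
    d2 = load_decomposition(path)
    assert isinstance(d2, CPDecomposition)
    np.testing.assert_array_equal(d2.weights, d.weights)
    np.testing.assert_array_equal(d2.factor_C, d.factor_C)
    assert d2.subject_id == "s1"

    T = hosvd(X, (3, 3, 3))
    path2 = tmp_path / "tucker.h5"
    save_decomposition(T, path2)
    T2 = load_decomposition(path2)
    np.testing.assert_array_equal(T2.core, T.core)
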