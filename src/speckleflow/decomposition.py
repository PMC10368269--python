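"""Low-rank decompositions of video tensors.

Two factorizations of a third-order cine-loop tensor ``X`` (rows x
columns x frames) are provided:

* the canonical polyadic decomposition (CPD)
  ``X ~ sum_r lambda_r a_r o b_r o c_r``, fitted by alternating least
  squares (ALS) on the Frobenius objective
  ``min || X - [Lambda; A, B, C] ||_F``; and
* the Tucker decomposition ``X ~ G x1 A x2 B x3 C`` computed by the
  truncated higher-order SVD (HOSVD), where the mode-n factor holds the
  leading left singular vectors of the mode-n unfolding and the core is
  ``G = X x1 A.T x2 B.T x3 C.T``.

The mode-3 ("frame") factor columns are temporal signals sampled at the
cine-loop frame rate; they carry the speckle-motion information that
downstream spectral analysis and classification consume.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Tuple

import h5py
import numpy as np

from .tensor_core import (
    frobenius_norm,
    khatri_rao,
    mode_n_product,
    unfold,
    validate_tensor3,
)

__all__ = [
    "CPDecomposition",
    "TuckerDecomposition",
    "cpd_als",
    "reconstruct_cpd",
    "hosvd",
    "reconstruct_tucker",
    "core_from_factors",
    "relative_error",
    "save_decomposition",
    "load_decomposition",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500


@dataclass
class CPDecomposition:
    """Rank-R canonical polyadic decomposition of a third-order tensor.

    Factor columns have unit Euclidean norm; all scale is absorbed into
    the non-negative weights ``weights`` (sorted non-increasing).
    """

    weights: np.ndarray  # (R,)
    factor_A: np.ndarray  # (I, R)
    factor_B: np.ndarray  # (J, R)
    factor_C: np.ndarray  # (K, R)
    n_iter: int = 0
    final_objective: float = np.nan
    objective_history: np.ndarray = field(default_factory=lambda: np.array([]))
    subject_id: str = ""
    site: str = ""

    @property
    def rank(self) -> int:
        return len(self.weights)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.factor_A.shape[0], self.factor_B.shape[0], self.factor_C.shape[0])


@dataclass
class TuckerDecomposition:
    """Tucker decomposition with orthonormal factors and dense core."""

    core: np.ndarray  # (R1, R2, R3)
    factor_A: np.ndarray  # (I, R1)
    factor_B: np.ndarray  # (J, R2)
    factor_C: np.ndarray  # (K, R3)
    subject_id: str = ""
    site: str = ""

    @property
    def ranks(self) -> Tuple[int, int, int]:
        return self.core.shape  # type: ignore[return-value]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.factor_A.shape[0], self.factor_B.shape[0], self.factor_C.shape[0])


def relative_error(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Relative reconstruction error ``||X - Xhat||_F / ||X||_F``."""
    X = np.asarray(X, dtype=np.float64)
    Xhat = np.asarray(Xhat, dtype=np.float64)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    nx = frobenius_norm(X)
    if nx == 0.0:
        raise ValueError("relative error is undefined for a zero tensor")
    return frobenius_norm(X - Xhat) / nx


def _leading_left_singular(M: np.ndarray, rank: int) -> np.ndarray:
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    return U[:, :rank]


def _init_factors(
    X: np.ndarray, rank: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """HOSVD-based initialization, random Gaussian where rank exceeds the mode."""
    factors = []
    for mode in (1, 2, 3):
        n = X.shape[mode - 1]
        if rank <= n:
            factors.append(_leading_left_singular(unfold(X, mode), rank))
        else:
            F = rng.standard_normal((n, rank))
            F /= np.linalg.norm(F, axis=0, keepdims=True)
            factors.append(F)
    return factors


def _normalize_columns(F: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(F, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return F / safe, norms


def cpd_als(
    X: np.ndarray,
    rank: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> CPDecomposition:
    """Fit a rank-``rank`` CPD by alternating least squares.

    Each sweep solves the linear least-squares problem for one factor
    with the other two fixed, via the normal equations
    ``A <- X(1) (C . B) [(C'C) * (B'B)]^+`` (``.`` Khatri-Rao, ``*``
    Hadamard) and cyclic analogues.  The relative reconstruction error
    is non-increasing across sweeps; iteration stops when its relative
    decrease falls below ``tol`` or after ``max_iter`` sweeps (the
    latter logs a warning but is not an error).

    Initialization uses the leading mode-n singular vectors (random
    Gaussian columns where ``rank`` exceeds a mode size), so the result
    is reproducible for a fixed ``seed``.
    """
    X = validate_tensor3(X)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    I, J, K = X.shape
    max_rank = min(J * K, I * K, I * J)
    if rank > max_rank:
        raise ValueError(f"rank {rank} exceeds the maximal CPD rank {max_rank} for shape {X.shape}")
    norm_x = frobenius_norm(X)
    if norm_x == 0.0:
        raise ValueError("cannot decompose a zero tensor")

    rng = np.random.default_rng(seed)
    A, B, C = _init_factors(X, rank, rng)
    X1 = unfold(X, 1)
    X2 = unfold(X, 2)
    X3 = unfold(X, 3)

    lam = np.ones(rank)
    prev_err = np.inf
    err = np.inf
    n_iter = 0
    converged = False
    history = []
    ridge = 1e-12 * np.eye(rank)  # guards rank-deficient Gram matrices

    for n_iter in range(1, max_iter + 1):
        # mode 1
        G = (C.T @ C) * (B.T @ B)
        A = np.linalg.solve(G + ridge, (X1 @ khatri_rao(C, B)).T).T
        A, _ = _normalize_columns(A)
        # mode 2
        G = (C.T @ C) * (A.T @ A)
        B = np.linalg.solve(G + ridge, (X2 @ khatri_rao(C, A)).T).T
        B, _ = _normalize_columns(B)
        # mode 3 (absorbs all scale)
        G = (B.T @ B) * (A.T @ A)
        M3 = X3 @ khatri_rao(B, A)
        C = np.linalg.solve(G + ridge, M3.T).T
        C, lam = _normalize_columns(C)

        # ||X - Xhat||^2 = ||X||^2 - 2<X, Xhat> + ||Xhat||^2 via Gram
        # matrices; M3 is the mode-3 MTTKRP already in hand.
        Cl = C * lam
        inner = float(np.sum(Cl * M3))
        norm_hat_sq = float(np.sum(G * (Cl.T @ Cl)))
        err_sq = max(norm_x**2 - 2.0 * inner + norm_hat_sq, 0.0)
        err = np.sqrt(err_sq) / norm_x
        if err < 1e-4:
            # the Gram shortcut loses ~8 digits to cancellation near exact
            # recovery; the explicit residual is exact (and cheap, since
            # only near-noiseless small tensors ever get here)
            err = frobenius_norm(X1 - (A * lam) @ khatri_rao(C, B).T) / norm_x
        history.append(err)
        if prev_err - err < tol * max(prev_err, 1e-300):
            converged = True
            break
        prev_err = err
    if not converged:
        logger.warning(
            "CPD-ALS reached max_iter=%d without meeting tol=%g (rel. error %.3g)",
            max_iter, tol, err,
        )

    # canonical ordering and signs: weights non-increasing; the
    # largest-magnitude entry of each temporal (mode-3) column is made
    # positive by a joint A/C flip, then A's largest entry by an A/B flip.
    order = np.argsort(-lam, kind="stable")
    lam, A, B, C = lam[order], A[:, order], B[:, order], C[:, order]
    sign_c = np.sign(C[np.argmax(np.abs(C), axis=0), np.arange(rank)])
    sign_c[sign_c == 0] = 1.0
    C *= sign_c
    A *= sign_c
    sign_a = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(rank)])
    sign_a[sign_a == 0] = 1.0
    A *= sign_a
    B *= sign_a

    return CPDecomposition(
        weights=lam, factor_A=A, factor_B=B, factor_C=C,
        n_iter=n_iter, final_objective=float(err),
        objective_history=np.asarray(history),
    )


def reconstruct_cpd(D: CPDecomposition) -> np.ndarray:
    """Rebuild ``sum_r lambda_r a_r o b_r o c_r`` as a dense tensor."""
    return np.einsum(
        "r,ir,jr,kr->ijk", D.weights, D.factor_A, D.factor_B, D.factor_C
    )


def hosvd(X: np.ndarray, ranks: Tuple[int, int, int]) -> TuckerDecomposition:
    """Truncated higher-order SVD.

    The mode-n factor holds the first ``ranks[n]`` left singular vectors
    of ``unfold(X, n)``; the core follows from :func:`core_from_factors`.
    The squared reconstruction error is bounded by the sum over modes of
    the discarded squared singular values (quasi-optimality).
    """
    X = validate_tensor3(X)
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != 3:
        raise ValueError("ranks must be a triple (R1, R2, R3)")
    for mode, r in enumerate(ranks, start=1):
        if not 1 <= r <= X.shape[mode - 1]:
            raise ValueError(
                f"rank {r} invalid for mode {mode} of size {X.shape[mode - 1]}"
            )
    factors = [
        _leading_left_singular(unfold(X, mode), ranks[mode - 1])
        for mode in (1, 2, 3)
    ]
    core = core_from_factors(X, *factors)
    return TuckerDecomposition(core=core, factor_A=factors[0],
                               factor_B=factors[1], factor_C=factors[2])


def core_from_factors(
    X: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Tucker core ``G = X x1 A.T x2 B.T x3 C.T``."""
    X = validate_tensor3(X)
    G = mode_n_product(X, np.asarray(A).T, 1)
    G = mode_n_product(G, np.asarray(B).T, 2)
    return mode_n_product(G, np.asarray(C).T, 3)


def reconstruct_tucker(D: TuckerDecomposition) -> np.ndarray:
    """Rebuild ``G x1 A x2 B x3 C`` as a dense tensor."""
    X = mode_n_product(D.core, D.factor_A, 1)
    X = mode_n_product(X, D.factor_B, 2)
    return mode_n_product(X, D.factor_C, 3)


def save_decomposition(
    D: CPDecomposition | TuckerDecomposition, path: os.PathLike | str
) -> None:
    """Persist a decomposition to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = D.subject_id
        f.attrs["site"] = D.site
        if isinstance(D, CPDecomposition):
            f.attrs["kind"] = "cpd"
            f.attrs["rank"] = D.rank
            f.attrs["n_iter"] = D.n_iter
            f.attrs["final_objective"] = D.final_objective
            f.create_dataset("weights", data=D.weights)
        else:
            f.attrs["kind"] = "tucker"
            f.attrs["ranks"] = D.ranks
            f.create_dataset("core", data=D.core)
        for name in ("factor_A", "factor_B", "factor_C"):
            f.create_dataset(name, data=getattr(D, name))


def load_decomposition(path: os.PathLike | str) -> CPDecomposition | TuckerDecomposition:
    """Load a decomposition saved by :func:`save_decomposition`."""
    with h5py.File(path, "r") as f:
        common = dict(
            factor_A=f["factor_A"][()],
            factor_B=f["factor_B"][()],
            factor_C=f["factor_C"][()],
            subject_id=str(f.attrs.get("subject_id", "")),
            site=str(f.attrs.get("site", "")),
        )
        if f.attrs["kind"] == "cpd":
            return CPDecomposition(
                weights=f["weights"][()],
                n_iter=int(f.attrs["n_iter"]),
                final_objective=float(f.attrs["final_objective"]),
                **common,
            )
        return TuckerDecomposition(core=f["core"][()], **common)
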