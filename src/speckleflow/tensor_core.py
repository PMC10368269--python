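"""Third-order tensor algebra primitives.

Unfolding, folding, mode-n products and the Khatri-Rao product, using
the Kolda-Bader convention throughout: the mode-n unfolding ``X(n)``
places mode-n fibers as columns, with the remaining modes enumerated so
that the lower-numbered mode varies fastest.  Modes are 1-based to
mirror the x1, x2, x3 notation used for tensor-decomposition models.

With this convention a rank-R canonical polyadic model satisfies
``unfold(X, 1) == A @ khatri_rao(C, B).T`` (and cyclic analogues),
which is the identity the alternating-least-squares normal equations
rely on.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import linalg as sla

__all__ = [
    "validate_tensor3",
    "unfold",
    "fold",
    "mode_n_product",
    "khatri_rao",
    "frobenius_norm",
]

Shape3 = Tuple[int, int, int]


def validate_tensor3(X: np.ndarray) -> np.ndarray:
    """Check that ``X`` is a finite third-order tensor and return it as float64."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"expected a third-order tensor, got ndim={X.ndim}")
    if min(X.shape) < 1:
        raise ValueError(f"all mode sizes must be >= 1, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains NaN or Inf")
    return X


def _check_mode(mode: int) -> int:
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    return mode


def unfold(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding of a third-order tensor.

    Element ``x[i, j, k]`` maps to row ``index(mode n)`` and a column
    index over the remaining modes with the lower-numbered mode varying
    fastest; the three unfoldings have shapes ``I x JK``, ``J x IK`` and
    ``K x IJ``.
    """
    X = validate_tensor3(X)
    mode = _check_mode(mode)
    return np.reshape(
        np.moveaxis(X, mode - 1, 0), (X.shape[mode - 1], -1), order="F"
    )


def fold(M: np.ndarray, mode: int, shape: Shape3) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the tensor of ``shape`` from ``M``."""
    mode = _check_mode(mode)
    M = np.asarray(M, dtype=np.float64)
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError(f"target shape must be a positive triple, got {shape}")
    other = [shape[m] for m in range(3) if m != mode - 1]
    expected = (shape[mode - 1], other[0] * other[1])
    if M.shape != expected:
        raise ValueError(
            f"matrix of shape {M.shape} does not match mode-{mode} unfolding "
            f"shape {expected} for tensor shape {shape}"
        )
    moved = np.reshape(M, (shape[mode - 1], *other), order="F")
    return np.moveaxis(moved, 0, mode - 1)


def mode_n_product(X: np.ndarray, M: np.ndarray, mode: int) -> np.ndarray:
    """Multiply every mode-n fiber of ``X`` by the matrix ``M``.

    Equivalent to ``fold(M @ unfold(X, mode), mode, new_shape)`` where
    the mode-n size becomes ``M.shape[0]``.
    """
    X = validate_tensor3(X)
    mode = _check_mode(mode)
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("M must be a matrix")
    if M.shape[1] != X.shape[mode - 1]:
        raise ValueError(
            f"matrix with {M.shape[1]} columns cannot act on mode {mode} of "
            f"size {X.shape[mode - 1]}"
        )
    new_shape = list(X.shape)
    new_shape[mode - 1] = M.shape[0]
    return fold(M @ unfold(X, mode), mode, tuple(new_shape))


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of ``A`` (I x R) and ``B`` (J x R).

    Column ``r`` of the result is ``kron(A[:, r], B[:, r])`` (IJ x R),
    the ordering under which ``unfold(X, 1) == A @ khatri_rao(C, B).T``
    for a canonical polyadic model.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("khatri_rao expects two matrices")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"column counts differ: {A.shape[1]} vs {B.shape[1]}"
        )
    return sla.khatri_rao(A, B)


def frobenius_norm(X: np.ndarray) -> float:
    """Frobenius norm of an array of any order."""
    return float(np.linalg.norm(np.asarray(X).ravel()))
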