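"""Bivariate tensor-product smooth construction.

The smooth f(t, FS) is built as a row-wise Kronecker product of two
marginal B-spline bases, with one difference penalty per marginal
direction (anisotropic smoothing), and a single sum-to-zero constraint
absorbed by an orthogonal reparameterization so the smooth is
identifiable next to a free intercept.

Column ordering is t-major throughout: the coefficient for (time basis
function i, flash-strength basis function j) sits at column ``i * k_fs + j``,
i.e. the FS index varies fastest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .splines import KnotVector, PenaltyMatrix


def row_kronecker(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product.

    Row r of the result is ``kron(A[r], B[r])``; with A the time basis and
    B the FS basis this realizes the t-major column ordering documented above.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError(f"row counts must match: {A.shape} vs {B.shape}")
    n, p = A.shape
    q = B.shape[1]
    return (A[:, :, None] * B[:, None, :]).reshape(n, p * q)


def row_kronecker_sparse(A: sparse.spmatrix, B: sparse.spmatrix) -> sparse.csr_matrix:
    """Sparse row-wise Kronecker with the same t-major column ordering.

    B-spline rows have at most degree+1 non-zeros, so the tensor design is
    very sparse; this keeps large fits cheap in memory.
    """
    A = sparse.csr_matrix(A)
    B = sparse.csr_matrix(B)
    if A.shape[0] != B.shape[0]:
        raise ValueError("row counts must match")
    q = B.shape[1]
    # scatter each column block a_i * B into columns [i*q, (i+1)*q)
    blocks = []
    for i in range(A.shape[1]):
        col = A.getcol(i)  # n x 1
        blocks.append(B.multiply(col))
    return sparse.hstack(blocks, format="csr")


def tensor_penalties(S_t: PenaltyMatrix, S_fs: PenaltyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-direction penalties on the tensor coefficient grid.

    Returns ``S_t ⊗ I`` (penalizes roughness along time) and ``I ⊗ S_fs``
    (along flash strength), under the t-major ordering.
    """
    k_t = S_t.n_basis
    k_fs = S_fs.n_basis
    P_t = np.kron(S_t.matrix, np.eye(k_fs))
    P_fs = np.kron(np.eye(k_t), S_fs.matrix)
    return P_t, P_fs


@dataclass(frozen=True)
class ConstraintMap:
    """Orthonormal map Z from k-1 free coefficients to the k-dim tensor space.

    Z spans the null space of the constraint row c (column sums of the
    tensor design over the fitting data), so B @ Z has zero column sums.
    Stored via c; Z is reconstructed deterministically by a Householder
    reflection, which keeps serialized models small.
    """

    c: np.ndarray

    @property
    def Z(self) -> np.ndarray:
        return householder_nullspace(self.c)


def householder_nullspace(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis (k x k-1) of the null space of a nonzero row vector c.

    Uses the Householder reflection H mapping c to ||c|| e1; columns 2..k of H
    are an orthonormal basis of c-perp. Deterministic given c.
    """
    c = np.asarray(c, dtype=float).ravel()
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("constraint vector is zero (all-zero design?)")
    v = c.copy()
    # sign choice avoids cancellation
    v[0] += np.copysign(norm, c[0] if c[0] != 0 else 1.0)
    H = np.eye(c.size) - 2.0 * np.outer(v, v) / (v @ v)
    return H[:, 1:]


def apply_constraint(
    tensor_design: np.ndarray | sparse.spmatrix,
    penalties: tuple[np.ndarray, np.ndarray],
):
    """Absorb the sum-to-zero identifiability constraint.

    The single linear constraint ``sum over fitting rows of each fitted
    smooth value = 0`` (equivalently c'θ = 0 with c the design column sums)
    is absorbed by the orthonormal map Z: the constrained design is B Z and
    each penalty becomes Z' S Z, preserving symmetry and positive
    semi-definiteness. The dimension drops by exactly one and the span of
    {intercept} ∪ {constrained columns} equals that of
    {intercept} ∪ {original columns}.

    Returns ``(constrained design, (P_t_c, P_fs_c), ConstraintMap)``.
    """
    if sparse.issparse(tensor_design):
        if tensor_design.shape[1] < 2:
            raise ValueError("tensor design must have at least 2 columns")
        c = np.asarray(tensor_design.sum(axis=0)).ravel()
    else:
        tensor_design = np.asarray(tensor_design, dtype=float)
        if tensor_design.shape[1] < 2:
            raise ValueError("tensor design must have at least 2 columns")
        c = tensor_design.sum(axis=0)
    cmap = ConstraintMap(c=c)
    Z = cmap.Z
    Xc = tensor_design @ Z
    if sparse.issparse(Xc):  # spmatrix @ dense -> np.matrix in some paths
        Xc = np.asarray(Xc)
    constrained = tuple(Z.T @ P @ Z for P in penalties)
    return Xc, constrained, cmap


@dataclass(frozen=True)
class TensorSmooth:
    """Frozen description of the constrained tensor-product smooth.

    Holds the two marginal knot vectors, whether FS is modelled on a log10
    scale, and the constraint map; everything needed to rebuild prediction
    rows for new (t, FS) points.
    """

    kv_t: KnotVector
    kv_fs: KnotVector
    fs_log_scale: bool
    cmap: ConstraintMap

    @property
    def k_t(self) -> int:
        return self.kv_t.n_basis

    @property
    def k_fs(self) -> int:
        return self.kv_fs.n_basis

    @property
    def dim(self) -> int:
        """Constrained coefficient dimension k_t * k_fs - 1."""
        return self.k_t * self.k_fs - 1

    def fs_coord(self, fs: np.ndarray) -> np.ndarray:
        fs = np.asarray(fs, dtype=float)
        return np.log10(fs) if self.fs_log_scale else fs

    def design_rows(self, t: np.ndarray, fs: np.ndarray) -> np.ndarray:
        """Constrained tensor design rows for paired (t, fs) vectors."""
        from .splines import bspline_design

        Bt = bspline_design(np.atleast_1d(t), self.kv_t)
        Bf = bspline_design(self.fs_coord(np.atleast_1d(fs)), self.kv_fs)
        return row_kronecker(Bt, Bf) @ self.cmap.Z
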