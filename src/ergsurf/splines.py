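"""One-dimensional B-spline bases and discrete difference penalties.

These are the marginal building blocks of the bivariate tensor-product
smooth: a B-spline basis on evenly spaced knots extended beyond the data
domain (the P-spline convention), and the difference penalty ``D'D`` that
penalizes wiggliness of the coefficient sequence rather than an integrated
derivative.  Uniform knot spacing everywhere — including past the domain
ends — is what makes polynomials of degree below the penalty order exactly
penalty-free: their coefficient sequences are polynomial in the index, so
the difference operator annihilates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


class SplineRangeError(ValueError):
    """Evaluation point outside the knot range (no silent extrapolation)."""


@dataclass(frozen=True)
class KnotVector:
    """Knot sequence for a univariate B-spline basis.

    Parameters
    ----------
    knots
        Non-decreasing breakpoints in the units of the covariate
        (ms for time, Td.s for flash strength).  The basis is valid on the
        base interval ``[knots[degree], knots[-degree-1]]``.
    degree
        Polynomial degree of the basis (3 = cubic).
    """

    knots: np.ndarray
    degree: int

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if self.degree < 0:
            raise ValueError("degree must be non-negative")
        if np.any(np.diff(knots) < 0):
            raise ValueError("knots must be non-decreasing")
        if self.n_basis < self.degree + 1:
            raise ValueError("too few knots for the requested degree")
        if self.lo >= self.hi:
            raise ValueError("empty base interval")

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def lo(self) -> float:
        """Lower end of the base interval (where the basis sums to one)."""
        return float(self.knots[self.degree])

    @property
    def hi(self) -> float:
        return float(self.knots[-self.degree - 1])


def place_knots(x_min: float, x_max: float, n_basis: int, degree: int = 3) -> KnotVector:
    """Evenly spaced knots covering ``[x_min, x_max]`` with ``n_basis`` functions.

    P-spline layout: ``n_basis - degree`` equal segments on the domain and
    ``degree`` extra uniform knots beyond each end, so every basis function
    is an identical shifted kernel and difference penalties leave low-order
    polynomials exactly unpenalized.
    """
    if not x_max > x_min:
        raise ValueError(f"degenerate interval [{x_min}, {x_max}]")
    if n_basis < degree + 1:
        raise ValueError(f"n_basis={n_basis} must be >= degree+1={degree + 1}")
    h = (x_max - x_min) / (n_basis - degree)
    knots = x_min + (np.arange(n_basis + degree + 1) - degree) * h
    # pin the domain ends exactly despite floating-point accumulation
    knots[degree] = x_min
    knots[-degree - 1 if degree else -1] = x_max
    return KnotVector(knots=knots, degree=degree)


def bspline_design(x: np.ndarray, kv: KnotVector) -> np.ndarray:
    """Evaluate the B-spline basis at ``x``; rows are a partition of unity.

    Raises :class:`SplineRangeError` for points outside the knot range.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size and (x.min() < kv.lo or x.max() > kv.hi):
        bad = x[(x < kv.lo) | (x > kv.hi)]
        raise SplineRangeError(
            f"evaluation points outside knot range [{kv.lo}, {kv.hi}]: {bad[:5]}"
        )
    M = BSpline.design_matrix(x, kv.knots, kv.degree, extrapolate=False)
    return M.toarray()


def bspline_design_sparse(x: np.ndarray, kv: KnotVector):
    """Sparse (CSR) variant of :func:`bspline_design`, for large fits."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size and (x.min() < kv.lo or x.max() > kv.hi):
        raise SplineRangeError(f"evaluation points outside knot range [{kv.lo}, {kv.hi}]")
    return BSpline.design_matrix(x, kv.knots, kv.degree, extrapolate=False)


@dataclass(frozen=True)
class PenaltyMatrix:
    """Symmetric PSD difference penalty ``S = D'D`` over basis coefficients.

    Polynomial coefficient sequences of degree < ``order`` lie in the null
    space, so the penalty leaves an ``order``-dimensional space unpenalized.
    """

    matrix: np.ndarray
    order: int

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[0]


def difference_penalty(n_basis: int, order: int = 2) -> PenaltyMatrix:
    """Order-``order`` discrete difference penalty for ``n_basis`` coefficients."""
    if order < 1:
        raise ValueError("difference order must be >= 1")
    if order >= n_basis:
        raise ValueError(f"order={order} must be < n_basis={n_basis}")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyMatrix(matrix=D.T @ D, order=order)
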