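"""Penalized B-spline (P-spline) smoothers.

Nonlinear terms — the temperature response f(TP) and the long-term calendar
trend f(T) — are represented as cubic B-spline expansions on equidistant
knots, regularized by a second-order random-walk (RW2) penalty on the
coefficients.  The RW2 penalty K = D2' D2 has a two-dimensional null space
(constant and linear coefficient sequences), so as the smoothing variance
shrinks to zero the fit collapses to a straight line; this realizes the
"natural" boundary behaviour without explicit natural-spline constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "bspline_basis", "second_difference_penalty"]

_DEGREE = 3  # cubic


@dataclass
class SplineBasis:
    """Cubic B-spline basis with its RW2 penalty.

    Attributes
    ----------
    knots : ndarray
        Full (padded) knot vector of length ``m + 4``.
    basis : ndarray of shape (n, m)
        Design matrix; rows sum to one on the covariate range.
    penalty : ndarray of shape (m, m)
        K = D2' D2, symmetric positive semidefinite with rank ``m - 2``.
    x_range : (float, float)
        Covariate range the basis spans.
    """

    knots: np.ndarray
    basis: np.ndarray
    penalty: np.ndarray
    x_range: tuple[float, float]
    degree: int = field(default=_DEGREE)

    @property
    def n_basis(self) -> int:
        return self.basis.shape[1]

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at new covariate values (clipped to the range)."""
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()


def _knot_vector(xmin: float, xmax: float, m: int) -> np.ndarray:
    # m cubic basis functions need m - 3 interior intervals plus 3 padding
    # knots on each side, all equidistant
    inner = np.linspace(xmin, xmax, m - 2)
    h = inner[1] - inner[0]
    return np.concatenate(
        [xmin - h * np.arange(3, 0, -1), inner, xmax + h * np.arange(1, 4)]
    )


def bspline_basis(x, m: int) -> SplineBasis:
    """Cubic B-spline basis of ``m`` functions on equidistant knots.

    Parameters
    ----------
    x : array-like
        Covariate values; the knots span ``[min(x), max(x)]``.
    m : int
        Number of basis functions, at least 4.

    Returns
    -------
    SplineBasis
        Basis matrix (partition of unity on the range) plus the RW2 penalty.
    """
    x = np.asarray(x, dtype=float)
    if m < 4:
        raise ValueError(f"need at least 4 basis functions, got m={m}")
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmin == xmax:
        raise ValueError("covariate is constant; cannot place a knot grid")
    t = _knot_vector(xmin, xmax, m)
    B = BSpline.design_matrix(x, t, _DEGREE).toarray()
    K = second_difference_penalty(m)
    return SplineBasis(knots=t, basis=B, penalty=K, x_range=(xmin, xmax))


def second_difference_penalty(m: int) -> np.ndarray:
    """RW2 penalty matrix K = D2' D2 for ``m`` coefficients.

    D2 is the ``(m - 2) x m`` second-difference matrix with stencil
    ``(1, -2, 1)``.  K annihilates constant and linear coefficient vectors and
    has rank ``m - 2``.
    """
    if m < 3:
        raise ValueError(f"second differences need m >= 3, got m={m}")
    D2 = np.diff(np.eye(m), n=2, axis=0)
    return D2.T @ D2
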