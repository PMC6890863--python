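"""Cardinal cubic regression spline basis with second-derivative penalty.

The basis is parameterized by the function *values at the knots*: a
natural cubic spline interpolates the k coefficients, so each basis
function equals 1 at its own knot and 0 at the others (cardinality).
Evaluation outside the knot range extrapolates linearly.  The penalty
is the integrated squared second derivative, a k x k positive
semi-definite matrix of rank k - 2 whose null space is spanned by
constant and linear functions of the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CRBasis", "cr_basis"]


def _natural_spline_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band matrices D ((k-2) x k) and B ((k-2) x (k-2)) linking knot values
    to interior second derivatives of the natural interpolating spline:
    B @ gamma = D @ beta."""
    h = np.diff(knots)
    k = knots.size
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    return D, B


@dataclass(frozen=True)
class CRBasis:
    """Cubic regression spline basis on fixed knots.

    Attributes
    ----------
    knots:
        Strictly increasing knot locations (k of them).
    penalty:
        k x k integrated-squared-second-derivative penalty matrix,
        symmetric PSD of rank k - 2.
    F:
        k x k map from coefficients (knot values) to knot second
        derivatives (first and last rows zero: natural conditions).
    """

    knots: np.ndarray
    penalty: np.ndarray
    F: np.ndarray

    @property
    def k(self) -> int:
        return self.knots.size

    def evaluate(self, x) -> np.ndarray:
        """Design matrix: rows are basis evaluations at each x.

        Inside the knot range this is piecewise-cubic interpolation of
        the coefficient vector; outside it extrapolates linearly from
        the boundary value and slope.
        """
        x = np.asarray(x, dtype=float).ravel()
        kn, F = self.knots, self.F
        k = kn.size
        X = np.zeros((x.size, k))
        h = np.diff(kn)

        inside = (x >= kn[0]) & (x <= kn[-1])
        if np.any(inside):
            xi = x[inside]
            j = np.clip(np.searchsorted(kn, xi, side="right") - 1, 0, k - 2)
            xl, xr = kn[j], kn[j + 1]
            hj = h[j]
            am = (xr - xi) / hj
            ap = (xi - xl) / hj
            cm = ((xr - xi) ** 3 / hj - hj * (xr - xi)) / 6.0
            cp = ((xi - xl) ** 3 / hj - hj * (xi - xl)) / 6.0
            rows = np.zeros((xi.size, k))
            rows[np.arange(xi.size), j] += am
            rows[np.arange(xi.size), j + 1] += ap
            rows += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
            X[inside] = rows

        for side, mask in (("lo", x < kn[0]), ("hi", x > kn[-1])):
            if not np.any(mask):
                continue
            if side == "lo":
                x0 = kn[0]
                val = np.zeros(k)
                val[0] = 1.0
                # slope of first segment at left knot (natural: gamma_0 = 0)
                slope = np.zeros(k)
                slope[0] -= 1.0 / h[0]
                slope[1] += 1.0 / h[0]
                slope -= h[0] / 6.0 * (2.0 * F[0] + F[1])
            else:
                x0 = kn[-1]
                val = np.zeros(k)
                val[-1] = 1.0
                slope = np.zeros(k)
                slope[-2] -= 1.0 / h[-1]
                slope[-1] += 1.0 / h[-1]
                slope += h[-1] / 6.0 * (F[-2] + 2.0 * F[-1])
            X[mask] = val + (x[mask] - x0)[:, None] * slope
        return X

    def null_space(self) -> np.ndarray:
        """k x 2 orthonormal basis of the penalty null space (constant + linear)."""
        N = np.column_stack([np.ones(self.k), self.knots])
        q, _ = np.linalg.qr(N)
        return q


def cr_basis(x, k: int = 10) -> CRBasis:
    """Build a CR basis with knots at the k quantiles of the data ``x``.

    Raises
    ------
    ValueError
        If fewer than k distinct values are supplied or k < 4.
    """
    if k < 4:
        raise ValueError(f"basis dimension k must be >= 4, got {k}")
    x = np.asarray(x, dtype=float).ravel()
    uniq = np.unique(x)
    if uniq.size < k:
        raise ValueError(f"need >= {k} distinct covariate values, got {uniq.size}")
    knots = np.quantile(uniq, np.linspace(0, 1, k))
    knots = np.unique(knots)
    if knots.size < k:  # heavy ties: fall back to even spacing over range
        knots = np.linspace(uniq[0], uniq[-1], k)
    D, B = _natural_spline_matrices(knots)
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0
    F = np.vstack([np.zeros(k), Binv_D, np.zeros(k)])
    return CRBasis(knots=knots, penalty=S, F=F)
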