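"""Penalized regression splines for cluster centroids.

Centroids are one-dimensional smooth functions of time fitted to pooled,
irregularly spaced (time, score) points with many duplicate abscissae.
The smoother is a low-rank penalized B-spline: a cubic B-spline basis of
modest dimension (default 8) spanning a fixed domain, with a
second-order difference penalty on the coefficients and the smoothing
parameter chosen by generalized cross-validation (GCV) over a log-spaced
grid.  In one dimension this is the same class of smoother as a low-rank
thin-plate regression spline: both are penalized least-squares fits in a
small spline basis, differing only in basis parameterization.

When a cluster holds fewer distinct time points than a cubic basis
needs, the basis degenerates gracefully to a straight line or a
constant.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import BSpline

from astraj.errors import InvalidInputError

_LAMBDA_GRID = np.logspace(-5.0, 5.0, 31)


class PenalizedSpline:
    """A penalized cubic B-spline smoother on a fixed domain.

    Parameters
    ----------
    domain:
        Closed interval the fitted function must be evaluable on,
        regardless of where the data lie.  Defaults to (0, 10) years.
    ndof:
        Basis dimension (number of B-spline coefficients) before any
        degeneracy reduction.  This bounds the effective degrees of
        freedom from above.
    degree:
        Spline degree; cubic by default.

    Attributes
    ----------
    edf:
        Effective degrees of freedom, trace of the hat matrix at the
        selected smoothing parameter (exact parameter count for the
        degenerate polynomial fallback).
    lambda_:
        Selected smoothing parameter (``None`` for the fallback).
    """

    def __init__(self, domain: tuple[float, float] = (0.0, 10.0), ndof: int = 8,
                 degree: int = 3):
        if ndof < degree + 1:
            raise InvalidInputError(f"ndof must be >= degree+1, got {ndof}")
        self.domain = (float(domain[0]), float(domain[1]))
        self.ndof = int(ndof)
        self.degree = int(degree)
        self.edf: float | None = None
        self.lambda_: float | None = None
        self._bspline: BSpline | None = None
        self._poly: np.polynomial.Polynomial | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray,
            weights: np.ndarray | None = None) -> "PenalizedSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0 or x.shape != y.shape:
            raise InvalidInputError("x and y must be equal-length and non-empty")
        lo, hi = self.domain
        if x.min() < lo - 1e-9 or x.max() > hi + 1e-9:
            raise InvalidInputError("data outside the spline domain")
        w = np.ones_like(x) if weights is None else np.asarray(weights, float)

        n_unique = np.unique(x).size
        ndof = min(self.ndof, max(x.size, 1))
        if n_unique < self.degree + 1 or ndof < self.degree + 1:
            if ndof < self.ndof:
                warnings.warn(
                    f"only {x.size} points for a {self.ndof}-dof basis; "
                    "falling back to a low-order polynomial", stacklevel=2)
            return self._fit_poly(x, y, w, n_unique)

        t = self._knots()
        B = BSpline.design_matrix(np.clip(x, lo, hi), t, self.degree).toarray()
        k = B.shape[1]
        # second-order difference penalty (discrete curvature)
        D = np.diff(np.eye(k), n=2, axis=0)
        P = D.T @ D
        BtB = B.T @ (B * w[:, None])
        Bty = B.T @ (w * y)
        n = x.size

        best = None
        for lam in _LAMBDA_GRID:
            A = BtB + lam * P + 1e-10 * np.eye(k)
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            coef = Ainv @ Bty
            fitted = B @ coef
            rss = float(np.sum(w * (y - fitted) ** 2))
            edf = float(np.trace(Ainv @ BtB))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, coef, edf)
        _, lam, coef, edf = best
        self.lambda_ = float(lam)
        self.edf = edf
        self._bspline = BSpline(t, coef, self.degree, extrapolate=True)
        return self

    def _fit_poly(self, x, y, w, n_unique):
        deg = min(n_unique - 1, 1)
        coef = np.polynomial.polynomial.polyfit(x, y, deg, w=np.sqrt(w))
        self._poly = np.polynomial.Polynomial(coef)
        self.edf = float(deg + 1)
        self.lambda_ = None
        return self

    def _knots(self) -> np.ndarray:
        lo, hi = self.domain
        n_interior = self.ndof - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate([
            np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)])

    # -- evaluation --------------------------------------------------------

    def __call__(self, x) -> np.ndarray:
        if self._bspline is None and self._poly is None:
            raise InvalidInputError("spline not fitted")
        x = np.asarray(x, dtype=float)
        if self._poly is not None:
            return self._poly(x)
        lo, hi = self.domain
        return self._bspline(np.clip(x, lo, hi))

    def grid(self, num: int = 101) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate on an even grid over the domain."""
        xs = np.linspace(self.domain[0], self.domain[1], num)
        return xs, self(xs)
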