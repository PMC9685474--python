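"""Cubic regression spline basis with an exact curvature penalty.

The basis is the "values at knots" parameterisation of a natural cubic
spline: basis function ``b_j`` is the natural cubic interpolant taking the
value 1 at knot ``j`` and 0 at every other knot.  A coefficient vector is
therefore directly interpretable as the spline's values at the knots, and
the penalty matrix ``S`` gives the integrated squared second derivative of
the fitted curve exactly, ``beta' S beta = int f''(x)^2 dx``.

Outside the knot range the spline is continued linearly (a natural spline
has zero second derivative at its boundary knots, so the linear extension
is the unique C1 continuation with no added curvature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "quantile_knots", "equally_spaced_knots"]


def quantile_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at quantiles of the *unique* observed values.

    The extremes are always included; interior knots sit at equally spaced
    probability levels of the unique-value distribution.
    """
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct values, got {ux.size}"
        )
    probs = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(ux, probs)
    knots = np.unique(knots)
    if knots.size < n_knots:
        raise ValueError("quantile knots collapsed; too few distinct values")
    return knots


def equally_spaced_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots equally spaced over [min(x), max(x)]."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("cannot place equally spaced knots on a constant series")
    return np.linspace(lo, hi, n_knots)


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic regression spline defined by its knot sequence.

    Parameters
    ----------
    knots
        Strictly increasing knot locations; the number of basis functions
        equals the number of knots.
    """

    knots: np.ndarray
    _F: np.ndarray = field(init=False, repr=False, compare=False)
    _S: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise ValueError("need at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)
        k = knots.size
        h = np.diff(knots)
        # B maps interior second derivatives, D maps knot values; the
        # natural-spline condition gives m = B^{-1} D beta at interior knots.
        B = np.zeros((k - 2, k - 2))
        D = np.zeros((k - 2, k))
        for i in range(k - 2):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = h[i + 1] / 6.0
                B[i + 1, i] = h[i + 1] / 6.0
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        Binv_D = np.linalg.solve(B, D)
        F = np.zeros((k, k))  # second derivatives at all knots (0 at ends)
        F[1:-1, :] = Binv_D
        object.__setattr__(self, "_F", F)
        object.__setattr__(self, "_S", D.T @ Binv_D)

    @property
    def n_basis(self) -> int:
        return self.knots.size

    def penalty(self) -> np.ndarray:
        """Exact integrated-squared-second-derivative penalty matrix."""
        return self._S.copy()

    def design(self, x: np.ndarray, extrapolate: bool = True):
        """Evaluate all basis functions at ``x``.

        Returns ``(X, n_extrapolated)`` where ``X`` is ``(len(x), n_basis)``
        and ``n_extrapolated`` counts points outside the knot range (these
        use the linear extension when ``extrapolate`` is true, and raise
        otherwise).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        knots, F = self.knots, self._F
        k = knots.size
        h = np.diff(knots)
        below = x < knots[0]
        above = x > knots[-1]
        n_out = int(below.sum() + above.sum())
        if n_out and not extrapolate:
            raise ValueError(f"{n_out} points outside the knot range")

        xc = np.clip(x, knots[0], knots[-1])
        j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
        hj = h[j]
        dl = xc - knots[j]          # distance from left knot
        dr = knots[j + 1] - xc      # distance to right knot
        a_l = dr / hj
        a_r = dl / hj
        c_l = (dr**3 / hj - hj * dr) / 6.0
        c_r = (dl**3 / hj - hj * dl) / 6.0

        X = np.zeros((x.size, k))
        rows = np.arange(x.size)
        X[rows, j] += a_l
        X[rows, j + 1] += a_r
        X += c_l[:, None] * F[j, :] + c_r[:, None] * F[j + 1, :]

        if n_out:
            # linear continuation: f(x0) + (x - x0) f'(x0) at each boundary
            for mask, x0 in ((below, knots[0]), (above, knots[-1])):
                if not mask.any():
                    continue
                v = self._boundary_rows(x0)
                d = self._boundary_slope_rows(x0)
                X[mask, :] = v[None, :] + (x[mask] - x0)[:, None] * d[None, :]
        return X, n_out

    def _boundary_rows(self, x0: float) -> np.ndarray:
        row = np.zeros(self.n_basis)
        idx = 0 if x0 == self.knots[0] else self.n_basis - 1
        row[idx] = 1.0
        return row

    def _boundary_slope_rows(self, x0: float) -> np.ndarray:
        knots, F = self.knots, self._F
        h = np.diff(knots)
        row = np.zeros(self.n_basis)
        if x0 == knots[0]:
            row[0] -= 1.0 / h[0]
            row[1] += 1.0 / h[0]
            # c_l' = -h/3, c_r' = -h/6 at the left end of the first interval
            row += (-h[0] / 3.0) * F[0, :] + (-h[0] / 6.0) * F[1, :]
        else:
            row[-2] -= 1.0 / h[-1]
            row[-1] += 1.0 / h[-1]
            # c_l' = h/6, c_r' = h/3 at the right end of the last interval
            row += (h[-1] / 6.0) * F[-2, :] + (h[-1] / 3.0) * F[-1, :]
        return row
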