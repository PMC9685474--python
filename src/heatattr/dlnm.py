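"""Distributed-lag nonlinear model: cross-basis, Poisson fit, lag-risk surface.

The cross-basis is the tensor product of an exposure basis (natural cubic
spline with knots equally spaced over the observed exposure range) and a
lag basis over lags 0..``lag_max`` (natural cubic spline with knots equally
spaced on the log-lag scale, or an unconstrained one-indicator-per-lag
basis).  Entry ``(i, j*K + k)`` is ``sum_l b_j(x_{i-l}) c_k(l)``; with the
indicator lag basis this reduces to the lag-stratified design built column
by column.

Relative risks are predicted against a reference exposure (by convention
the 70th percentile of the analyzed series): ``RR(x, l) = exp([v(x,l) -
v(ref,l)]' theta)`` with ``v(x,l)_{jk} = b_j(x) c_k(l)``, so the surface is
exactly 1 at the reference for every lag.  Confidence bounds come from the
delta method on the Poisson coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .basis import SplineBasis, equally_spaced_knots
from .smooth import _dummy_columns

__all__ = ["CrossBasis", "DLNMFit", "RRSurface", "build_cross_basis", "fit_dlnm", "cross_pred"]


def _lag_basis(lag_max: int, kind: str, n_knots: int = 3) -> np.ndarray:
    """Basis matrix over lags 0..lag_max, one row per lag."""
    lags = np.arange(lag_max + 1, dtype=float)
    if lag_max == 0:
        return np.ones((1, 1))
    if kind == "indicator":
        return np.eye(lag_max + 1)
    if kind == "cr":
        if lag_max < 2 or n_knots < 3:
            return np.column_stack([np.ones(lag_max + 1), lags])
        # knots equally spaced on the log(1 + lag) scale
        log_knots = np.linspace(0.0, np.log1p(lag_max), n_knots)
        knots = np.expm1(log_knots)
        b = SplineBasis(knots)
        C, _ = b.design(lags)
        return C
    raise ValueError(f"unknown lag basis kind {kind!r}")


@dataclass
class CrossBasis:
    """Exposure x lag tensor design with the metadata to predict from it."""

    matrix: np.ndarray          # (n, J*K), gauge-reduced: last exposure fn dropped
    exposure_basis: SplineBasis
    lag_matrix: np.ndarray      # (lag_max+1, K)
    lag_max: int
    incomplete: np.ndarray      # rows lacking full lag history
    x: np.ndarray = field(repr=False, default=None)
    lag_kind: str = "cr"

    @property
    def n_exposure(self) -> int:
        return self.exposure_basis.n_basis

    @property
    def n_lag(self) -> int:
        return self.lag_matrix.shape[1]


def build_cross_basis(
    x,
    lag_max: int = 5,
    n_exposure_knots: int = 5,
    lag_kind: str = "cr",
    n_lag_knots: int = 3,
    exposure_knots=None,
) -> CrossBasis:
    """Build the exposure x lag cross-basis for a daily exposure series.

    The first ``lag_max`` rows lack a complete lag history and are flagged
    (excluded from fitting).  The exposure spline, being a partition of
    unity, is gauge-fixed by dropping its last basis function within each
    lag-basis column; relative-risk contrasts are invariant to this choice.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= lag_max:
        raise ValueError(f"series of length {n} is too short for lag_max={lag_max}")
    if exposure_knots is None:
        exposure_knots = equally_spaced_knots(x, n_exposure_knots)
    eb = SplineBasis(np.asarray(exposure_knots, dtype=float))
    B, _ = eb.design(x)                # (n, J)
    C = _lag_basis(lag_max, lag_kind, n_lag_knots)  # (L+1, K)
    J, K = B.shape[1], C.shape[1]

    full = np.zeros((n, J * K))
    for lag in range(lag_max + 1):
        Bl = np.zeros_like(B)
        Bl[lag:, :] = B[: n - lag, :]
        # outer product over basis dims, accumulated across lags
        full += np.repeat(Bl, K, axis=1) * np.tile(C[lag, :], J)[None, :]

    # drop exposure basis function J-1 within every lag column (gauge fix)
    keep = np.ones(J * K, dtype=bool)
    keep[(J - 1) * K :] = False
    incomplete = np.zeros(n, dtype=bool)
    incomplete[:lag_max] = True
    return CrossBasis(
        matrix=full[:, keep],
        exposure_basis=eb,
        lag_matrix=C,
        lag_max=lag_max,
        incomplete=incomplete,
        x=x,
        lag_kind=lag_kind,
    )


@dataclass
class DLNMFit:
    """Poisson fit of counts on a cross-basis plus seasonal controls."""

    coef_cb: np.ndarray
    vcov_cb: np.ndarray
    cb: CrossBasis
    converged: bool
    deviance: float
    n_obs: int
    fitted: np.ndarray = None  # fitted means on the complete rows


def fit_dlnm(cb: CrossBasis, counts, covariates: pd.DataFrame | None = None) -> DLNMFit:
    """Fit a Poisson log-link model: counts ~ cross-basis + seasonal terms.

    Rows with incomplete lag history are excluded.  ``covariates`` is a
    data frame of categorical seasonal controls (typically month and year).
    """
    y = np.asarray(counts, dtype=float)
    if y.size != cb.matrix.shape[0]:
        raise ValueError("counts length does not match the cross-basis")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    keep = ~cb.incomplete
    Xcb = cb.matrix[keep]
    ncb = Xcb.shape[1]
    parts = [np.ones((keep.sum(), 1)), Xcb]
    if covariates is not None and len(covariates.columns):
        Xc, _, _ = _dummy_columns(covariates.loc[keep].reset_index(drop=True))
        parts.append(Xc)
    X = np.column_stack(parts)
    model = sm.GLM(y[keep], X, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely
        raise RuntimeError(f"Poisson DLNM fit failed: {exc}") from exc
    if not res.converged:
        raise RuntimeError("Poisson DLNM fit did not converge")
    sl = slice(1, 1 + ncb)
    return DLNMFit(
        coef_cb=res.params[sl],
        vcov_cb=np.asarray(res.cov_params())[sl, sl],
        cb=cb,
        converged=True,
        deviance=float(res.deviance),
        n_obs=int(keep.sum()),
        fitted=np.asarray(res.fittedvalues),
    )


@dataclass
class RRSurface:
    """Lag-specific relative risks on an exposure grid, with 95% bounds."""

    exposures: np.ndarray       # (G,)
    lags: np.ndarray            # (L+1,)
    rr: np.ndarray              # (G, L+1)
    lo: np.ndarray
    hi: np.ndarray
    reference: float

    def to_frame(self) -> pd.DataFrame:
        g, l = np.meshgrid(self.exposures, self.lags, indexing="ij")
        return pd.DataFrame(
            {
                "exposure": g.ravel(),
                "lag": l.ravel().astype(int),
                "rr": self.rr.ravel(),
                "lo": self.lo.ravel(),
                "hi": self.hi.ravel(),
            }
        )


def _contrast(cb: CrossBasis, x: float, ref: float, lag: int) -> np.ndarray:
    """Gauge-reduced contrast vector for RR(x, lag) vs the reference."""
    bx, _ = cb.exposure_basis.design(np.array([x]))
    br, _ = cb.exposure_basis.design(np.array([ref]))
    db = (bx - br).ravel()              # (J,)
    c = cb.lag_matrix[lag, :]           # (K,)
    v = np.outer(db, c).ravel()         # (J*K,)
    K = cb.n_lag
    return v[: (cb.n_exposure - 1) * K]  # drop gauge-fixed block


def cross_pred(
    fit: DLNMFit,
    reference: float | None = None,
    ref_percentile: float = 70.0,
    exposures: np.ndarray | None = None,
    level: float = 0.95,
) -> RRSurface:
    """Predict lag-specific relative risks against a reference exposure.

    The reference defaults to the ``ref_percentile`` (70th) percentile of
    the analyzed exposure series and must lie within its range.
    """
    cb = fit.cb
    lo_x, hi_x = float(cb.x.min()), float(cb.x.max())
    if reference is None:
        reference = float(np.percentile(cb.x, ref_percentile))
    if not (lo_x <= reference <= hi_x):
        raise ValueError(
            f"reference {reference} outside the exposure range [{lo_x}, {hi_x}]"
        )
    if exposures is None:
        exposures = np.linspace(lo_x, hi_x, 30)
    exposures = np.unique(np.append(np.asarray(exposures, dtype=float), reference))

    z = sps.norm.ppf(0.5 + level / 2.0)
    lags = np.arange(cb.lag_max + 1)
    G = exposures.size
    rr = np.empty((G, lags.size))
    lo = np.empty_like(rr)
    hi = np.empty_like(rr)
    for gi, xv in enumerate(exposures):
        for lag in lags:
            v = _contrast(cb, xv, reference, lag)
            eta = float(v @ fit.coef_cb)
            se = float(np.sqrt(max(v @ fit.vcov_cb @ v, 0.0)))
            rr[gi, lag] = np.exp(eta)
            lo[gi, lag] = np.exp(eta - z * se)
            hi[gi, lag] = np.exp(eta + z * se)
    # exact identity at the reference point
    ref_idx = int(np.argmin(np.abs(exposures - reference)))
    rr[ref_idx, :] = 1.0
    lo[ref_idx, :] = 1.0
    hi[ref_idx, :] = 1.0
    return RRSurface(exposures, lags, rr, lo, hi, float(reference))
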