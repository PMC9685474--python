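"""Penalized-spline exposure-response models for HRI rates.

Fits ``log E[rate] = intercept + f(tmax) + calendar effects`` where ``f`` is
a natural cubic regression spline with an integrated-squared-curvature
penalty.  The smoothing parameter is chosen by generalized cross validation
(GCV) over a deterministic log-spaced grid with one level of local
refinement.  Two exponential families are supported, both with log link:

* ``"gamma"`` — daily rates per 100,000 (strictly positive response), the
  default for the exposure-response model;
* ``"poisson"`` — daily counts, used by the distributed-lag path.

The smooth is identified by centering its design columns over the training
points and carrying an explicit intercept; calendar covariates enter as
treatment-coded indicator columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .basis import SplineBasis, quantile_knots

__all__ = [
    "Design",
    "SmoothFit",
    "build_design",
    "build_spline_basis",
    "fit_smooth",
    "predict_rate",
    "compare_models",
    "ConvergenceError",
]

MAX_BASIS = 5  # published analyses cap cubic regression bases at 5 knots


class ConvergenceError(RuntimeError):
    """Penalized IRLS failed to converge."""


def build_spline_basis(
    x: np.ndarray, n_basis: int, max_basis: int = MAX_BASIS, knots=None
):
    """Spline basis with knots at quantiles of the unique observed values.

    Returns ``(basis, design_matrix)``; ``n_basis`` may not exceed
    ``max_basis``.  Explicit ``knots`` override the quantile rule.
    """
    if n_basis > max_basis:
        raise ValueError(f"n_basis={n_basis} exceeds the cap of {max_basis}")
    if n_basis < 3:
        raise ValueError("n_basis must be at least 3")
    basis = SplineBasis(
        quantile_knots(x, n_basis) if knots is None else np.asarray(knots, float)
    )
    X, _ = basis.design(np.asarray(x, dtype=float))
    return basis, X


@dataclass
class Design:
    """Assembled model matrix: intercept | (centered) smooth | covariates."""

    X: np.ndarray
    penalty: np.ndarray
    smooth_slice: slice
    smooth_centers: np.ndarray
    basis: SplineBasis | None
    covariate_levels: dict[str, list]
    column_names: list[str]
    linear: bool = False
    x_train_range: tuple[float, float] | None = None


def _dummy_columns(covariates: pd.DataFrame, levels: dict[str, list] | None = None):
    """Treatment-coded indicators; first level of each factor is reference.

    When ``levels`` is given (prediction time), unseen levels map to the
    reference with a warning.
    """
    cols, names = [], []
    out_levels: dict[str, list] = {}
    for name in covariates.columns:
        vals = covariates[name].astype(str).to_numpy()
        if levels is None:
            cats = sorted(pd.unique(vals).tolist())
        else:
            cats = levels[name]
            unseen = set(vals) - set(cats)
            if unseen:
                warnings.warn(
                    f"covariate {name!r}: {len(unseen)} unseen level(s) "
                    f"{sorted(unseen)} mapped to reference {cats[0]!r}"
                )
        out_levels[name] = list(cats)
        for lev in cats[1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{name}[{lev}]")
    if cols:
        return np.column_stack(cols), names, out_levels
    return np.empty((len(covariates), 0)), names, out_levels


def build_design(
    x: np.ndarray,
    n_basis: int | None = 4,
    covariates: pd.DataFrame | None = None,
    *,
    linear: bool = False,
    max_basis: int = MAX_BASIS,
    knots=None,
) -> Design:
    """Build the full model matrix for :func:`fit_smooth`.

    ``linear=True`` replaces the spline by a single straight-line term (no
    penalty); used for reduction to an ordinary GLM.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if linear:
        basis, Xs = None, x[:, None].copy()
        centers = Xs.mean(axis=0)
        Xs = Xs - centers
        pen = None
    else:
        basis, Xs = build_spline_basis(x, n_basis, max_basis=max_basis, knots=knots)
        centers = Xs.mean(axis=0)
        Xs = Xs - centers
        # The values-at-knots basis is a partition of unity, so after
        # centering the columns sum to zero and the constant direction is
        # unidentifiable (the penalty annihilates it as well).  Fix the
        # gauge by dropping the last column; fitted smooth and penalty
        # value are invariant to this choice.
        pen = basis.penalty()[:-1, :-1]
        Xs = Xs[:, :-1]
    k = Xs.shape[1]

    if covariates is not None and len(covariates.columns) > 0:
        if len(covariates) != n:
            raise ValueError("covariates length does not match x")
        Xc, cov_names, levels = _dummy_columns(covariates)
    else:
        Xc, cov_names, levels = np.empty((n, 0)), [], {}

    X = np.column_stack([np.ones(n), Xs, Xc])
    p = X.shape[1]
    S = np.zeros((p, p))
    if basis is not None:
        S[1 : 1 + k, 1 : 1 + k] = pen
    names = (
        ["intercept"]
        + [f"s(x).{j}" for j in range(k)]
        + cov_names
    )
    return Design(
        X=X,
        penalty=S,
        smooth_slice=slice(1, 1 + k),
        smooth_centers=centers,
        basis=basis,
        covariate_levels=levels,
        column_names=names,
        linear=linear,
        x_train_range=(float(x.min()), float(x.max())),
    )


# ---------------------------------------------------------------------------
# families

def _deviance(y, mu, family):
    if family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * np.sum(t - (y - mu))
    if family == "gamma":
        return 2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu)
    raise ValueError(f"unknown family {family!r}")


def _irls_weights(y, mu, family):
    # log link: w = (dmu/deta)^2 / V(mu)
    if family == "poisson":
        return mu
    return np.ones_like(mu)  # gamma: mu^2 / mu^2


def _check_response(y, family, index=None):
    y = np.asarray(y, dtype=float)
    if family == "gamma" and np.any(y <= 0):
        bad = np.nonzero(y <= 0)[0]
        labels = (
            [str(index[i]) for i in bad[:10]]
            if index is not None
            else bad[:10].tolist()
        )
        raise ValueError(
            f"gamma family requires strictly positive response; "
            f"{bad.size} offending observation(s), first: {labels}"
        )
    if family == "poisson" and np.any(y < 0):
        raise ValueError("poisson family requires non-negative response")
    return y


def _pirls(y, X, S, lam, family, max_iter=200, tol=1e-8):
    """Penalized IRLS; returns (beta, mu, deviance, edf, converged)."""
    n = y.size
    mu = y + 0.5 if family == "poisson" else y.copy()
    eta = np.log(mu)
    dev = _deviance(y, mu, family)
    beta = None
    P = lam * S
    for _ in range(max_iter):
        w = _irls_weights(y, mu, family)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X
        beta = np.linalg.solve(A + P, XtW @ z)
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        new_dev = _deviance(y, mu, family)
        if abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            w = _irls_weights(y, mu, family)
            XtW = X.T * w
            A = XtW @ X
            edf = float(np.trace(np.linalg.solve(A + P, A)))
            return beta, mu, dev, edf, True
        dev = new_dev
    return beta, mu, dev, np.nan, False


@dataclass
class SmoothFit:
    """A fitted penalized-spline model plus everything needed to predict."""

    coef: np.ndarray
    lam: float
    family: str
    edf: float
    deviance: float
    null_deviance: float
    deviance_explained: float
    aic: float
    gcv: float
    dispersion: float
    n_obs: int
    basis: SplineBasis | None
    smooth_centers: np.ndarray
    covariate_levels: dict[str, list]
    column_names: list[str]
    linear: bool
    x_train_range: tuple[float, float] | None
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def has_covariates(self) -> bool:
        return bool(self.covariate_levels)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "coef": self.coef.tolist(),
            "lam": self.lam,
            "family": self.family,
            "edf": self.edf,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "deviance_explained": self.deviance_explained,
            "aic": self.aic,
            "gcv": self.gcv,
            "dispersion": self.dispersion,
            "n_obs": self.n_obs,
            "knots": None if self.basis is None else self.basis.knots.tolist(),
            "smooth_centers": self.smooth_centers.tolist(),
            "covariate_levels": self.covariate_levels,
            "column_names": self.column_names,
            "linear": self.linear,
            "x_train_range": self.x_train_range,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SmoothFit":
        d = json.loads(s)
        basis = None if d["knots"] is None else SplineBasis(np.array(d["knots"]))
        rng = d["x_train_range"]
        return cls(
            coef=np.array(d["coef"]),
            lam=d["lam"],
            family=d["family"],
            edf=d["edf"],
            deviance=d["deviance"],
            null_deviance=d["null_deviance"],
            deviance_explained=d["deviance_explained"],
            aic=d["aic"],
            gcv=d["gcv"],
            dispersion=d["dispersion"],
            n_obs=d["n_obs"],
            basis=basis,
            smooth_centers=np.array(d["smooth_centers"]),
            covariate_levels={k: list(v) for k, v in d["covariate_levels"].items()},
            column_names=list(d["column_names"]),
            linear=d["linear"],
            x_train_range=None if rng is None else (rng[0], rng[1]),
        )


DEFAULT_LAM_GRID = np.logspace(-4, 7, 45)


def fit_smooth(
    y: np.ndarray,
    design: Design,
    family: str = "gamma",
    lam_grid: np.ndarray | None = None,
    index=None,
    refine: bool = True,
) -> SmoothFit:
    """Fit the penalized model, selecting the penalty weight by GCV.

    ``GCV(lam) = n * D(lam) / (n - edf(lam))^2`` with ``D`` the family
    deviance and ``edf`` the trace of the influence matrix.  The grid is
    fixed, so the selection is fully deterministic.  ``index`` (e.g. dates)
    is only used to label offending observations in error messages.
    """
    y = _check_response(y, family, index)
    X, S = design.X, design.penalty
    n = y.size
    if X.shape[0] != n:
        raise ValueError("design and response lengths differ")

    unpenalized = design.linear or not np.any(S)
    if lam_grid is None:
        lam_grid = np.array([0.0]) if unpenalized else DEFAULT_LAM_GRID
    lam_grid = np.atleast_1d(np.asarray(lam_grid, dtype=float))

    def eval_lam(lam):
        beta, mu, dev, edf, ok = _pirls(y, X, S, lam, family)
        if not ok:
            return None
        gcv = n * dev / (n - edf) ** 2
        return beta, mu, dev, edf, gcv

    results = {}
    for lam in lam_grid:
        r = eval_lam(lam)
        if r is not None:
            results[lam] = r
    if not results:
        raise ConvergenceError(
            f"penalized IRLS failed to converge for every lambda in the grid "
            f"(family={family}, n={n}, p={X.shape[1]})"
        )
    best = min(results, key=lambda l: results[l][4])

    if refine and len(lam_grid) > 2 and best > 0:
        idx = int(np.nonzero(lam_grid == best)[0][0])
        lo = lam_grid[max(idx - 1, 0)]
        hi = lam_grid[min(idx + 1, len(lam_grid) - 1)]
        if lo > 0 and hi > lo:
            for lam in np.logspace(np.log10(lo), np.log10(hi), 15):
                r = eval_lam(lam)
                if r is not None:
                    results[lam] = r
            best = min(results, key=lambda l: results[l][4])

    beta, mu, dev, edf, gcv = results[best]

    # intercept-only fit of the same family for deviance explained
    mu0 = np.full(n, y.mean())
    null_dev = _deviance(y, mu0, family)
    dev_expl = 1.0 - dev / null_dev if null_dev > 0 else 0.0

    if family == "gamma":
        pearson = np.sum((y - mu) ** 2 / mu**2)
        dispersion = pearson / max(n - edf, 1.0)
        # full gamma log-likelihood with shape 1/dispersion; the dispersion
        # is an estimated parameter, so it enters the AIC penalty.  A
        # deviance/dispersion quasi-AIC is not comparable across models
        # because each model's own dispersion rescales its deviance.
        shape = 1.0 / dispersion
        loglik = np.sum(
            shape * np.log(shape)
            - shape * np.log(mu)
            + (shape - 1.0) * np.log(y)
            - shape * y / mu
            - special.gammaln(shape)
        )
        aic = -2.0 * loglik + 2.0 * (edf + 1.0)
    else:
        dispersion = 1.0
        loglik = np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0))
        aic = -2.0 * loglik + 2.0 * edf

    return SmoothFit(
        coef=beta,
        lam=float(best),
        family=family,
        edf=edf,
        deviance=float(dev),
        null_deviance=float(null_dev),
        deviance_explained=float(dev_expl),
        aic=float(aic),
        gcv=float(gcv),
        dispersion=float(dispersion),
        n_obs=n,
        basis=design.basis,
        smooth_centers=design.smooth_centers,
        covariate_levels=design.covariate_levels,
        column_names=design.column_names,
        linear=design.linear,
        x_train_range=design.x_train_range,
        fitted=mu,
    )


def predict_rate(
    fit: SmoothFit,
    x: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Predicted mean rate (or count) at new exposure values.

    Covariates must be supplied exactly when the fit was trained with them.
    Points beyond the training exposure range use the spline's linear
    extension; their number is reported in a warning.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if fit.has_covariates and covariates is None:
        raise ValueError("fit includes calendar covariates; supply them")
    if not fit.has_covariates and covariates is not None and len(covariates.columns):
        raise ValueError("fit has no covariates but covariates were passed")

    if fit.linear:
        Xs, n_out = x[:, None].copy(), 0
    else:
        Xs, n_out = fit.basis.design(x)
        Xs = Xs - fit.smooth_centers
        Xs = Xs[:, :-1]  # same gauge as training (see build_design)
    if n_out:
        warnings.warn(
            f"{n_out} point(s) outside the training exposure range "
            f"{fit.x_train_range}; linear spline extension used"
        )
    if fit.linear:
        Xs = Xs - fit.smooth_centers

    if fit.has_covariates:
        Xc, _, _ = _dummy_columns(covariates, levels=fit.covariate_levels)
    else:
        Xc = np.empty((x.size, 0))
    X = np.column_stack([np.ones(x.size), Xs, Xc])
    return np.exp(X @ fit.coef)


def compare_models(fits: dict[str, SmoothFit]) -> pd.DataFrame:
    """Rank candidate fits by AIC (ascending; ties by deviance explained).

    All candidates must have been fit to the same response (checked via
    length and null deviance).
    """
    items = list(fits.items())
    if not items:
        raise ValueError("no fits to compare")
    n0 = items[0][1].n_obs
    nd0 = items[0][1].null_deviance
    for name, f in items:
        if f.n_obs != n0 or abs(f.null_deviance - nd0) > 1e-8 * (abs(nd0) + 1):
            raise ValueError(f"fit {name!r} was not fit to the same response")
    df = pd.DataFrame(
        {
            "metric": [name for name, _ in items],
            "aic": [f.aic for _, f in items],
            "dev_expl": [f.deviance_explained for _, f in items],
            "edf": [f.edf for _, f in items],
        }
    )
    return df.sort_values(
        by=["aic", "dev_expl"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
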