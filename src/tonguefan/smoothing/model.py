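"""Penalized least-squares fitting with REML smoothing-parameter selection.

The model is ``y = X beta + e`` with quadratic penalties
``sum_j lambda_j beta' S_j beta``.  Smoothing parameters minimize the
(profiled, Gaussian) restricted-likelihood score

    V(log lambda) = (n - Mp)/2 * log(RSS + penalty)
                    + 1/2 * ( log|X'X + S_lambda| - log|S_lambda|_+ )

where Mp is the total penalty null-space dimension (including
unpenalized columns).  AR(1) residual correlation along each contour is
handled by a two-stage procedure: fit with independent errors, pool the
lag-1 autocorrelation of within-contour residuals, whiten rows, refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .design import DesignInfo, ModelSpec, build_design

__all__ = [
    "SmoothFit",
    "fit",
    "fit_smooth_1d",
    "estimate_ar1",
    "predict",
    "adjusted_r2",
    "check_basis",
]


@dataclass
class SmoothFit:
    """A fitted penalized-spline additive mixed model."""

    design: DesignInfo
    beta: np.ndarray
    lambdas: np.ndarray
    Vb: np.ndarray
    sigma2: float
    edf: dict
    edf_total: float
    r2_adj: float
    ar_phi: float
    n_rows: int
    rss: float
    tss: float
    converged: bool
    reml_history: list = field(default_factory=list)
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    ar_groups: np.ndarray | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec


def _penalized_system(info: DesignInfo, lambdas: np.ndarray, XtX: np.ndarray):
    A = XtX.copy()
    for b in info.blocks:
        b.add_to(A, lambdas)
    return A


def _reml_score(loglam, info, XtX, Xty, yty, n):
    lambdas = np.exp(np.clip(loglam, -30.0, 30.0))
    A = _penalized_system(info, lambdas, XtX)
    try:
        cf = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        return 1e300, None  # finite so numeric differencing stays well-defined
    beta = cho_solve(cf, Xty)
    rss = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 0.0)
    pen = float(beta @ (A @ beta) - beta @ (XtX @ beta))
    pen = max(pen, 0.0)
    mp = info.null_space_dim
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    logdet_S = sum(b.logdet_plus(lambdas) for b in info.blocks)
    score = 0.5 * ((n - mp) * np.log(rss + pen + 1e-300) + logdet_A - logdet_S)
    if not np.isfinite(score):
        return 1e300, None
    return float(score), (beta, rss, pen, cf)


def _optimize_lambdas(info, XtX, Xty, yty, n, max_iter=200, tol=1e-7):
    """Quasi-Newton REML optimization over log-lambda with grid fallback."""
    nl = info.n_lambda
    history: list[float] = []
    best = {"score": np.inf, "loglam": None}

    def objective(loglam):
        s, _ = _reml_score(loglam, info, XtX, Xty, yty, n)
        if s < best["score"] - 0.0:
            if not history or s < history[-1]:
                history.append(s)
            best["score"] = s
            best["loglam"] = np.asarray(loglam, dtype=float).copy()
        return s

    # coarse grid initialization (shared value across lambdas) ...
    for g in np.linspace(-10.0, 12.0, 12):
        objective(np.full(nl, g))
    # ... then cyclic coordinate refinement: penalty blocks can have very
    # different optimal scales (e.g. random curves fully shrunk while the
    # reference smooth stays wiggly), and a shared start strands the
    # quasi-Newton step in the wrong basin
    marks = np.array([-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0, 16.0])
    for _ in range(2 if nl > 1 else 0):
        for j in range(nl):
            base = best["loglam"].copy()
            for m in marks:
                trial = base.copy()
                trial[j] = m
                objective(trial)
    x0 = best["loglam"].copy()

    converged = False
    try:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(-25.0, 25.0)] * nl,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
        )
        converged = bool(res.success) or abs(res.fun - best["score"]) < 1e-6
    except Exception:  # pragma: no cover - defensive
        pass

    if best["loglam"] is None:  # pragma: no cover
        raise RuntimeError("REML optimization failed to produce any finite score")
    if not converged:
        warnings.warn("REML optimizer did not report convergence; using best score seen")
    return best["loglam"], history, converged


def estimate_ar1(residuals, groups) -> float:
    """Pooled lag-1 autocorrelation of residuals within each group.

    ``phi = sum r_t r_{t-1} / sum r_{t-1}^2`` over consecutive
    within-group pairs, clipped to [0, 0.99].
    """
    r = np.asarray(residuals, dtype=float)
    g = np.asarray(groups)
    if r.size != g.size:
        raise ValueError("residuals and groups must have equal length")
    same = g[1:] == g[:-1]
    if not np.any(same):
        raise ValueError("no within-group consecutive residual pairs")
    num = float(np.sum(r[1:][same] * r[:-1][same]))
    den = float(np.sum(r[:-1][same] ** 2))
    if den == 0:
        raise ValueError("degenerate residuals (zero variance)")
    return float(np.clip(num / den, 0.0, 0.99))


def _whiten(X: np.ndarray, y: np.ndarray, groups: np.ndarray, phi: float):
    """AR(1) prewhitening along consecutive rows within each group."""
    Xw = X.copy()
    yw = y.copy()
    same = np.empty(len(y), dtype=bool)
    same[0] = False
    same[1:] = groups[1:] == groups[:-1]
    first = ~same
    c0 = np.sqrt(1.0 - phi * phi)
    Xw[same] = X[same] - phi * X[np.flatnonzero(same) - 1]
    yw[same] = y[same] - phi * y[np.flatnonzero(same) - 1]
    Xw[first] *= c0
    yw[first] *= c0
    return Xw, yw


def _solve_and_summarize(info, X, y, loglam, history, converged, phi, groups):
    n = len(y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    score, payload = _reml_score(loglam, info, XtX, Xty, yty, n)
    if payload is None:
        raise np.linalg.LinAlgError("singular penalized system at optimum")
    beta, rss, pen, cf = payload
    lambdas = np.exp(loglam)
    Ainv = cho_solve(cf, np.eye(info.ncol))
    Fmat = Ainv @ XtX
    edf_diag = np.diag(Fmat)
    edf = {name: float(edf_diag[sl].sum()) for name, sl in info.term_slices.items()}
    edf_total = float(edf_diag.sum())
    mp = info.null_space_dim
    sigma2 = (rss + pen) / max(n - mp, 1)
    Vb = sigma2 * Ainv
    Vb = (Vb + Vb.T) / 2.0
    fitted = X @ beta
    resid = y - fitted
    ybar = float(np.mean(y))
    tss = float(np.sum((y - ybar) ** 2))
    denom = n - edf_total
    if denom <= 0:
        raise ValueError("effective degrees of freedom exhaust the sample size")
    r2 = 1.0 - (rss / denom) / (tss / (n - 1)) if tss > 0 else 1.0
    return SmoothFit(
        design=info,
        beta=beta,
        lambdas=lambdas,
        Vb=Vb,
        sigma2=float(sigma2),
        edf=edf,
        edf_total=edf_total,
        r2_adj=float(r2),
        ar_phi=float(phi),
        n_rows=n,
        rss=float(rss),
        tss=tss,
        converged=converged,
        reml_history=history,
        fitted=fitted,
        residuals=resid,
        ar_groups=groups,
    )


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    lambdas: np.ndarray | None = None,
    min_rows: int = 100,
) -> SmoothFit:
    """Fit the model described by ``spec`` to the long-format ``table``.

    Rows must be ordered so that points of one contour (``spec.ar_group``)
    are consecutive; AR(1) whitening runs along that order.  Passing
    ``lambdas`` skips REML selection and uses the given smoothing
    parameters (one per penalty).

    Raises
    ------
    ValueError
        If fewer than ``min_rows`` rows are supplied.
    """
    if len(table) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {len(table)}")
    info = build_design(spec, table)
    y = np.asarray(table[spec.response], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if spec.ar_group in table.columns:
        groups = table[spec.ar_group].to_numpy()
    else:
        groups = np.arange(len(y))  # every row its own contour: no AR pairs

    def solve(X_, y_, phi):
        n_ = len(y_)
        XtX = X_.T @ X_
        Xty = X_.T @ y_
        yty = float(y_ @ y_)
        if lambdas is not None:
            ll = np.log(np.asarray(lambdas, dtype=float))
            if ll.size != info.n_lambda:
                raise ValueError(
                    f"expected {info.n_lambda} lambdas, got {ll.size}"
                )
            return _solve_and_summarize(info, X_, y_, ll, [], True, phi, groups)
        ll, hist, conv = _optimize_lambdas(info, XtX, Xty, yty, n_)
        return _solve_and_summarize(info, X_, y_, ll, hist, conv, phi, groups)

    phi_spec = spec.ar_phi
    if isinstance(phi_spec, str):  # "estimate"
        fit0 = solve(info.X, y, 0.0)
        try:
            phi = estimate_ar1(fit0.residuals, groups)
        except ValueError:
            return fit0
        if phi < 1e-3:
            return fit0
        Xw, yw = _whiten(info.X, y, groups, phi)
        return solve(Xw, yw, phi)
    phi = float(phi_spec)
    if phi == 0.0:
        return solve(info.X, y, 0.0)
    Xw, yw = _whiten(info.X, y, groups, phi)
    return solve(Xw, yw, phi)


def predict(
    fit_: SmoothFit, newdata: pd.DataFrame, include_random: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Point estimate and standard error for each row of ``newdata``."""
    M = fit_.design.rows(newdata, include_random=include_random)
    est = M @ fit_.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", M, fit_.Vb, M), 0.0))
    return est, se


def adjusted_r2(fit_: SmoothFit) -> float:
    """Adjusted R-squared, ``1 - (RSS/(n-EDF)) / (TSS/(n-1))``.

    Computed on the whitened scale when AR(1) correction is active.
    """
    return fit_.r2_adj


def check_basis(fit_: SmoothFit, edf_frac: float = 0.95) -> dict:
    """Per-term basis-adequacy report.

    For each smooth term, compares the achieved EDF with the maximum
    available (``k'``, the number of coefficients of the term) and flags
    terms whose EDF sits within 5% of the ceiling — a sign that the
    basis dimension may be limiting the fit.  Also reports the residual
    lag-1 autocorrelation.
    """
    report: dict = {"terms": {}, "residual_ar1": None}
    for name, sl in fit_.design.term_slices.items():
        k_prime = sl.stop - sl.start
        achieved = fit_.edf[name]
        report["terms"][name] = {
            "k_prime": k_prime,
            "edf": achieved,
            "flagged": achieved >= edf_frac * k_prime,
        }
    if fit_.residuals is not None and fit_.ar_groups is not None:
        try:
            report["residual_ar1"] = estimate_ar1(fit_.residuals, fit_.ar_groups)
        except ValueError:
            pass
    return report


class Smooth1D:
    """A single penalized spline fit of y on x (intercept + one smooth)."""

    def __init__(self, fit_: SmoothFit):
        self._fit = fit_

    def predict(self, x, se: bool = False):
        nd = pd.DataFrame({self._fit.spec.covariate: np.asarray(x, dtype=float)})
        est, s = predict(self._fit, nd)
        return (est, s) if se else est

    @property
    def fit(self) -> SmoothFit:
        return self._fit


def fit_smooth_1d(x, y, k: int = 10, lambdas=None) -> Smooth1D:
    """Convenience: penalized-spline scatterplot smoother."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame({"theta": x, "rho": y, "contour_id": 0})
    spec = ModelSpec(response="rho", factor=None, k=k, ar_phi=0.0)
    return Smooth1D(fit(spec, df, lambdas=lambdas, min_rows=min(len(df), 20)))
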