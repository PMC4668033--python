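"""Fixed- and mixed-effects fitting of the taper profile.

Three estimators share one data layout:

``fit_ols``
    Nonlinear least squares on the pooled sections (homoscedastic,
    independent errors).

``fit_gls``
    Gaussian maximum likelihood with the power-of-DBH variance function
    and optional within-tree CAR(1) correlation; the profile coefficients
    are re-solved by weighted least squares inside an outer search over
    (delta, phi).

``fit_foce``
    Two-level nonlinear mixed model by the first-order conditional
    expectation (FOCE) linearization, alternating in the style of
    Lindstrom & Bates: (i) predict every plot's and tree's random effects
    (EBLUPs) at the current estimates, (ii) linearize the profile around
    those EBLUPs and maximize the profiled ML or REML likelihood of the
    working linear mixed model over the variance parameters, with the
    fixed coefficients solved by generalized least squares.  The loop
    stops when the relative change of the -2 log-likelihood falls below
    ``rtol`` (default 1e-8) or after ``max_outer`` iterations.

Information criteria use k = (number of fixed coefficients) + (number of
free variance-covariance parameters); AIC = -2 loglik + 2k and
BIC = -2 loglik + ln(n) k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

from .calibration import calibrate
from .covariance import (
    RandomSpec,
    TaperMixedModel,
    VarComp,
    inv_log_cholesky,
    log_cholesky,
    variance_weights,
)
from .data_io import TaperDataset
from .exceptions import ConfigurationError, ConvergenceError, ValidationError
from .taper import FixedParams, PARAM_NAMES, _coef_arrays, _eval_profile

__all__ = ["FitResult", "fit_ols", "fit_gls", "fit_foce", "compare_models", "screen_active"]

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# flat data layout
# --------------------------------------------------------------------------
class _FlatData:
    """Observation-level arrays ordered plot-by-plot, tree-by-tree."""

    def __init__(self, data: TaperDataset):
        if data.n_trees == 0:
            raise ValidationError("empty dataset")
        self.plot_ids = data.plot_ids
        plots = data.plots()
        self.trees = [t for p in self.plot_ids for t in plots[p]]
        self.n_trees = len(self.trees)
        self.n_plots = len(self.plot_ids)
        self.plot_of_tree = np.array(
            [self.plot_ids.index(t.plot_id) for t in self.trees]
        )
        self.trees_of_plot = [
            [j for j, t in enumerate(self.trees) if t.plot_id == p]
            for p in self.plot_ids
        ]
        d, h, hi, y, tree_of_obs = [], [], [], [], []
        self.tree_slices: list[slice] = []
        row = 0
        for j, t in enumerate(self.trees):
            nj = len(t.sections)
            self.tree_slices.append(slice(row, row + nj))
            d.append(np.full(nj, t.d))
            h.append(np.full(nj, t.h))
            hi.append(t.section_heights)
            y.append(t.section_diameters)
            tree_of_obs.append(np.full(nj, j))
            row += nj
        self.d = np.concatenate(d)
        self.h = np.concatenate(h)
        self.hi = np.concatenate(hi)
        self.y = np.concatenate(y)
        self.tree_of_obs = np.concatenate(tree_of_obs)
        self.n = row
        self.d_tree = np.array([t.d for t in self.trees])
        self.plot_rows = [
            np.concatenate([np.arange(self.tree_slices[j].start, self.tree_slices[j].stop)
                            for j in js])
            for js in self.trees_of_plot
        ]
        # per-tree |h_k - h_k'| matrices for CAR(1)
        self.tree_dist = [
            np.abs(t.section_heights[:, None] - t.section_heights[None, :])
            for t in self.trees
        ]

    def predict(self, params: FixedParams, expanded: Sequence[str] = (),
                offsets: np.ndarray | None = None) -> np.ndarray:
        """Profile predictions with per-tree additive coefficient offsets."""
        c = {n: np.asarray(getattr(params, n), float) for n in PARAM_NAMES}
        if offsets is not None:
            for r, name in enumerate(expanded):
                c[name] = c[name] + offsets[self.tree_of_obs, r]
        return _eval_profile(self.d, self.h, self.hi, c, warn=False)

    def design(self, params: FixedParams, names: Sequence[str],
               expanded: Sequence[str] = (), offsets: np.ndarray | None = None
               ) -> np.ndarray:
        """Finite-difference derivative matrix w.r.t. the named coefficients."""
        cols = []
        for name in names:
            theta = getattr(params, name)
            step = max(1e-6, 1e-6 * abs(theta))
            up = params.with_values([name], [theta + step])
            dn = params.with_values([name], [theta - step])
            cols.append(
                (self.predict(up, expanded, offsets) - self.predict(dn, expanded, offsets))
                / (2.0 * step)
            )
        return np.stack(cols, axis=1)


# --------------------------------------------------------------------------
# result container
# --------------------------------------------------------------------------
@dataclass
class FitResult:
    """A fitted taper model: coefficients, uncertainty, fit statistics."""

    method: str
    params: FixedParams
    se: dict[str, float]
    sigma2: float
    loglik: float
    k: int
    n_obs: int
    n_fixed: int
    converged: bool
    varcomp: VarComp | None = None
    spec: RandomSpec | None = None
    eblups: dict | None = None
    iterations: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.k

    def mixed_model(self) -> TaperMixedModel:
        if self.spec is None or self.varcomp is None or self.varcomp.D_p is None:
            raise ConfigurationError("not a mixed-effects fit")
        return TaperMixedModel(self.params, self.spec, self.varcomp)

    def report(self) -> str:
        lines = [f"method: {self.method}", f"n_obs: {self.n_obs}",
                 f"loglik: {self.loglik:.4f}  AIC: {self.aic:.1f}  BIC: {self.bic:.1f}",
                 f"sigma2: {self.sigma2:.6g}", "coefficients:"]
        for n in self.params.active:
            lines.append(f"  {n:>3} = {getattr(self.params, n): .6g}"
                         f"  (se {self.se.get(n, float('nan')):.3g})")
        if self.varcomp is not None and self.varcomp.D_p is not None:
            vc = self.varcomp
            lines.append(f"delta: {vc.delta:.4f}  phi: {vc.phi}")
            lines.append(f"D_p diag: {np.diag(vc.D_p)}")
            lines.append(f"D_t diag: {np.diag(vc.D_t)}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# OLS
# --------------------------------------------------------------------------
def fit_ols(
    data: TaperDataset,
    active: Sequence[str] = PARAM_NAMES,
    start: FixedParams | None = None,
) -> FitResult:
    """Nonlinear ordinary least squares on the pooled sections."""
    start = start if start is not None else FixedParams(active=tuple(active))
    if tuple(start.active) != tuple(n for n in PARAM_NAMES if n in active):
        start = FixedParams(**{n: getattr(start, n) for n in active if n in PARAM_NAMES},
                            active=tuple(active))
    flat = _FlatData(data)
    names = start.active
    p = len(names)
    if flat.n <= p:
        raise ValidationError(f"underdetermined: {flat.n} observations, {p} parameters")
    x0 = start.as_array(names)

    def resid(bv):
        return flat.predict(start.with_values(names, bv)) - flat.y

    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12,
                                 gtol=1e-12, max_nfev=4000)
    if sol.status <= 0:
        raise ConvergenceError("OLS failed to converge", best=sol)
    params = start.with_values(names, sol.x)
    sse = float(2.0 * sol.cost)
    sigma2 = sse / (flat.n - p)
    JtJ = sol.jac.T @ sol.jac
    cov = sigma2 * np.linalg.inv(JtJ)
    se = {n: float(np.sqrt(cov[i, i])) for i, n in enumerate(names)}
    s2_ml = sse / flat.n
    loglik = -0.5 * flat.n * (_LOG2PI + np.log(s2_ml) + 1.0)
    return FitResult(
        method="OLS", params=params, se=se, sigma2=sigma2, loglik=loglik,
        k=p + 1, n_obs=flat.n, n_fixed=p, converged=True,
        iterations=int(sol.nfev),
    )


# --------------------------------------------------------------------------
# GLS
# --------------------------------------------------------------------------
def _whiten_factors(flat: _FlatData, delta: float, phi: float | None):
    """Per-tree Cholesky factors of g^2 M and the summed log-determinant."""
    g = variance_weights(flat.d_tree, delta)
    factors, logdet = [], 0.0
    for j, sl in enumerate(flat.tree_slices):
        nj = sl.stop - sl.start
        if phi is None or phi == 0.0:
            factors.append(g[j])  # scalar: G = g^2 I
            logdet += 2.0 * nj * np.log(g[j])
        else:
            M = phi ** flat.tree_dist[j]
            L = np.linalg.cholesky(M)
            factors.append((g[j], L))
            logdet += 2.0 * nj * np.log(g[j]) + 2.0 * np.sum(np.log(np.diag(L)))
    return factors, logdet


def _whiten(flat: _FlatData, r: np.ndarray, factors) -> np.ndarray:
    out = np.empty_like(r)
    from scipy.linalg import solve_triangular

    for sl, f in zip(flat.tree_slices, factors):
        if isinstance(f, tuple):
            g, L = f
            out[sl] = solve_triangular(L, r[sl], lower=True) / g
        else:
            out[sl] = r[sl] / f
    return out


def fit_gls(
    data: TaperDataset,
    active: Sequence[str] = PARAM_NAMES,
    variance: bool = True,
    car1: bool = True,
    start: FixedParams | None = None,
) -> FitResult:
    """Generalized nonlinear least squares (Gaussian ML) with power-of-DBH
    variance and optional within-tree CAR(1) correlation; delta and phi are
    estimated jointly with the coefficients."""
    start = start if start is not None else FixedParams(active=tuple(active))
    if tuple(start.active) != tuple(n for n in PARAM_NAMES if n in active):
        start = FixedParams(**{n: getattr(start, n) for n in active if n in PARAM_NAMES},
                            active=tuple(active))
    flat = _FlatData(data)
    names = start.active
    p = len(names)
    if flat.n <= p:
        raise ValidationError(f"underdetermined: {flat.n} observations, {p} parameters")

    beta_warm = {"x": fit_ols(data, active=names, start=start).params.as_array(names)}
    cache: dict = {}

    def inner(delta: float, phi: float | None):
        factors, logdet = _whiten_factors(flat, delta, phi)

        def resid(bv):
            r = flat.predict(start.with_values(names, bv)) - flat.y
            return _whiten(flat, r, factors)

        sol = optimize.least_squares(resid, beta_warm["x"], method="lm",
                                     xtol=1e-11, ftol=1e-11, gtol=1e-11, max_nfev=2000)
        beta_warm["x"] = sol.x
        rss = float(2.0 * sol.cost)
        n2l = flat.n * (_LOG2PI + np.log(rss / flat.n)) + logdet + flat.n
        return n2l, sol, rss, logdet

    if not variance and not car1:
        n2l, sol, rss, _ = inner(0.0, None)
        delta_hat, phi_hat = 0.0, None
    else:
        def obj(u):
            delta = u[0] if variance else 0.0
            phi = float(expit(u[-1])) if car1 else None
            return inner(delta, phi)[0]

        u0 = ([0.5] if variance else []) + ([0.0] if car1 else [])  # phi0 = 0.5
        res = optimize.minimize(obj, np.array(u0), method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
        if not res.success:
            raise ConvergenceError("GLS variance-parameter search failed", best=res)
        delta_hat = float(res.x[0]) if variance else 0.0
        phi_hat = float(expit(res.x[-1])) if car1 else None
        n2l, sol, rss, _ = inner(delta_hat, phi_hat)

    params = start.with_values(names, sol.x)
    sigma2 = rss / (flat.n - p)
    JtJ = sol.jac.T @ sol.jac
    cov = sigma2 * np.linalg.inv(JtJ)
    se = {n: float(np.sqrt(cov[i, i])) for i, n in enumerate(names)}
    k = p + 1 + (1 if variance else 0) + (1 if car1 else 0)
    return FitResult(
        method="GLS", params=params, se=se, sigma2=sigma2, loglik=-0.5 * n2l,
        k=k, n_obs=flat.n, n_fixed=p, converged=True,
        varcomp=VarComp(sigma2=sigma2, delta=delta_hat, phi=phi_hat),
    )


# --------------------------------------------------------------------------
# FOCE
# --------------------------------------------------------------------------
def _pack_indices(n_r: int) -> list[int]:
    """Positions of the (logged) diagonal entries in packed log-Cholesky order."""
    idx, k = [], 0
    for i in range(n_r):
        for j in range(i + 1):
            if i == j:
                idx.append(k)
            k += 1
    return idx


def _lme_profile(flat: _FlatData, X: np.ndarray, Z: np.ndarray, w: np.ndarray,
                 theta: np.ndarray, n_r: int, variance: bool, car1: bool,
                 reml: bool, p: int, zero_d: bool):
    """-2 profiled log-likelihood of the working linear mixed model.

    theta packs [log-chol Psi_p, log-chol Psi_t, delta?, logit(phi)?] where
    Psi = D / sigma2; beta and sigma2 are profiled out analytically.
    Returns (-2l, beta, sigma2, A) with A = sum X' V0^-1 X.
    """
    m = n_r * (n_r + 1) // 2
    if zero_d:
        Psi_p = Psi_t = np.zeros((n_r, n_r))
        rest = theta
    else:
        Psi_p = inv_log_cholesky(theta[:m], n_r)
        Psi_t = inv_log_cholesky(theta[m:2 * m], n_r)
        rest = theta[2 * m:]
    delta = float(rest[0]) if variance else 0.0
    phi = float(expit(rest[-1])) if car1 else None

    g_tree = variance_weights(flat.d_tree, delta)
    n = flat.n
    A = np.zeros((p, p))
    c = np.zeros(p)
    wVw = 0.0
    logdet = 0.0
    for i, rows in enumerate(flat.plot_rows):
        Xi, Zi, wi = X[rows], Z[rows], w[rows]
        V0 = Zi @ Psi_p @ Zi.T
        lo = 0
        for j in flat.trees_of_plot[i]:
            sl = flat.tree_slices[j]
            nj = sl.stop - sl.start
            loc = slice(lo, lo + nj)
            Zt = Z[sl]
            blk = Zt @ Psi_t @ Zt.T
            if phi is None:
                blk[np.diag_indices(nj)] += g_tree[j] ** 2
            else:
                blk += g_tree[j] ** 2 * phi ** flat.tree_dist[j]
            V0[loc, loc] += blk
            lo += nj
        try:
            cf = cho_factor(V0, lower=True)
        except np.linalg.LinAlgError:
            # near-singular working covariance at extreme theta: regularize
            # so the line search sees a finite, increasing objective
            jit = 1e-10 * max(float(np.trace(V0)) / max(len(rows), 1), 1e-30)
            try:
                cf = cho_factor(V0 + jit * np.eye(len(rows)), lower=True)
            except np.linalg.LinAlgError:
                return 1e12 * (1.0 + float(np.sum(theta**2))), None, None, None
        logdet += 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vx = cho_solve(cf, Xi)
        Vw = cho_solve(cf, wi)
        A += Xi.T @ Vx
        c += Xi.T @ Vw
        wVw += wi @ Vw
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    rss = max(float(wVw - c @ beta), 1e-300)
    if reml:
        sigma2 = rss / (n - p)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12 * (1.0 + float(np.sum(theta**2))), None, None, None
        n2l = (n - p) * (_LOG2PI + np.log(sigma2)) + logdet + logdetA + (n - p)
    else:
        sigma2 = rss / n
        n2l = n * (_LOG2PI + np.log(sigma2)) + logdet + n
    return float(n2l), beta, float(sigma2), A


def fit_foce(
    data: TaperDataset,
    spec: RandomSpec,
    active: Sequence[str] = PARAM_NAMES,
    criterion: str = "REML",
    variance: bool = True,
    car1: bool = False,
    start: FixedParams | None = None,
    max_outer: int = 200,
    rtol: float = 1e-8,
    zero_d: bool = False,
) -> FitResult:
    """Two-level nonlinear mixed fit by FOCE (Lindstrom-Bates alternation).

    ``spec.expanded`` must be a subset of the active coefficients.
    ``criterion`` is ``"ML"`` or ``"REML"``.  ``variance`` switches the
    power-of-DBH variance function on, ``car1`` the within-tree CAR(1)
    correlation.  ``zero_d=True`` is a diagnostic mode pinning both
    random-effect covariance matrices at zero (the fit then reduces to GLS).

    Raises :class:`ConvergenceError` (carrying the objective trace) when the
    alternation has not stabilised after ``max_outer`` iterations.
    """
    criterion = criterion.upper()
    if criterion not in {"ML", "REML"}:
        raise ConfigurationError(f"criterion must be ML or REML, got {criterion}")
    reml = criterion == "REML"
    active = tuple(n for n in PARAM_NAMES if n in active)
    if set(spec.expanded) - set(active):
        raise ConfigurationError("expanded parameters must be active")
    flat = _FlatData(data)
    names = active
    p = len(names)
    n_r = spec.n_r
    m = n_r * (n_r + 1) // 2
    exp_idx = [names.index(nm) for nm in spec.expanded]

    ols = fit_ols(data, active=names, start=start)
    params = ols.params
    sigma2 = ols.sigma2
    # starting covariances: D = 0.01 I  =>  Psi = D / sigma2
    psi0 = 0.01 / sigma2 * np.eye(n_r)
    theta = np.concatenate([
        np.array([]) if zero_d else np.concatenate([log_cholesky(psi0)] * 2),
        [0.5] if variance else [],
        [logit(0.5)] if car1 else [],
    ])
    diag_pos = _pack_indices(n_r)
    bounds: list[tuple[float, float]] = []
    if not zero_d:
        for blk in range(2):
            kk = 0
            for i in range(n_r):
                for j in range(i + 1):
                    bounds.append((-12.0, 3.0) if kk in diag_pos else (-15.0, 15.0))
                    kk += 1
    if variance:
        bounds.append((-2.0, 3.0))
    if car1:
        bounds.append((-7.0, 7.0))

    bp = np.zeros((flat.n_plots, n_r))
    bt = np.zeros((flat.n_trees, n_r))
    trace: list[float] = []
    prev = np.inf
    converged = False
    A_last = None
    for it in range(1, max_outer + 1):
        # --- (i) EBLUP step at current (beta, theta) ---------------------
        if not zero_d:
            Psi_p = inv_log_cholesky(theta[:m], n_r)
            Psi_t = inv_log_cholesky(theta[m:2 * m], n_r)
            rest = theta[2 * m:]
            vc = VarComp(
                sigma2=sigma2,
                D_p=sigma2 * Psi_p,
                D_t=sigma2 * Psi_t,
                delta=float(rest[0]) if variance else 0.0,
                phi=float(expit(rest[-1])) if car1 else None,
            )
            model = TaperMixedModel(params, spec, vc)
            for i, p_id in enumerate(flat.plot_ids):
                js = flat.trees_of_plot[i]
                cal = calibrate(model, [flat.trees[j] for j in js],
                                tol=1e-10, max_iter=100, raise_on_fail=False)
                bp[i] = [cal.plot_effects[nm] for nm in spec.expanded]
                for jj, j in enumerate(js):
                    bt[j] = [cal.tree_effects[flat.trees[j].tree_id][nm]
                             for nm in spec.expanded]

        # --- (ii) working linear mixed model -----------------------------
        offsets = bp[flat.plot_of_tree] + bt
        f0 = flat.predict(params, spec.expanded, offsets)
        X = flat.design(params, names, spec.expanded, offsets)
        Z = X[:, exp_idx]
        b_obs = offsets[flat.tree_of_obs]  # total effect per observation
        w = flat.y - f0 + X @ params.as_array(names) + np.einsum("ij,ij->i", Z, b_obs)

        res = optimize.minimize(
            lambda th: _lme_profile(flat, X, Z, w, th, n_r, variance, car1,
                                    reml, p, zero_d)[0],
            theta, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        n2l, beta, sigma2_new, A_last = _lme_profile(
            flat, X, Z, w, theta, n_r, variance, car1, reml, p, zero_d
        )
        if beta is None or not np.isfinite(n2l):
            raise ConvergenceError("FOCE working-model likelihood degenerate",
                                   trace=trace)
        params = params.with_values(names, beta)
        sigma2 = sigma2_new
        trace.append(n2l)
        if abs(n2l - prev) <= rtol * (abs(n2l) + 0.1):
            converged = True
            break
        prev = n2l

    if not converged:
        raise ConvergenceError(
            f"FOCE alternation did not stabilise in {max_outer} iterations",
            trace=trace,
        )

    if zero_d:
        D_p = D_t = np.zeros((n_r, n_r))
        rest = theta
    else:
        D_p = sigma2 * inv_log_cholesky(theta[:m], n_r)
        D_t = sigma2 * inv_log_cholesky(theta[m:2 * m], n_r)
        rest = theta[2 * m:]
        if min(np.min(np.diag(D_p)), np.min(np.diag(D_t))) < 1e-12 * sigma2:
            warnings.warn("a random-effect variance collapsed to the boundary; "
                          "returning the boundary fit", RuntimeWarning)
    delta_hat = float(rest[0]) if variance else 0.0
    phi_hat = float(expit(rest[-1])) if car1 else None
    vc = VarComp(sigma2=sigma2, D_p=D_p, D_t=D_t, delta=delta_hat, phi=phi_hat)

    # final EBLUPs at the converged estimates
    eblups = {"plot": {}, "tree": {}}
    if not zero_d:
        model = TaperMixedModel(params, spec, vc)
        for i, p_id in enumerate(flat.plot_ids):
            js = flat.trees_of_plot[i]
            cal = calibrate(model, [flat.trees[j] for j in js],
                            tol=1e-10, max_iter=100, raise_on_fail=False)
            eblups["plot"][p_id] = dict(cal.plot_effects)
            for j in js:
                t = flat.trees[j]
                eblups["tree"][(p_id, t.tree_id)] = dict(cal.tree_effects[t.tree_id])

    cov = sigma2 * np.linalg.inv(A_last)
    se = {nm: float(np.sqrt(cov[i, i])) for i, nm in enumerate(names)}
    k = p + 1 + (0 if zero_d else 2 * m) + (1 if variance else 0) + (1 if car1 else 0)
    return FitResult(
        method=f"FOCE-{criterion}", params=params, se=se, sigma2=sigma2,
        loglik=-0.5 * trace[-1], k=k, n_obs=flat.n, n_fixed=p, converged=True,
        varcomp=vc, spec=spec, eblups=eblups, iterations=len(trace),
    )


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------
def compare_models(
    results: Sequence[FitResult],
    names: Sequence[str] | None = None,
    nested: Sequence[tuple[int, int]] | None = None,
):
    """Tabulate fits (k, loglik, AIC, BIC) and test declared nested pairs.

    ``nested`` lists (reduced, full) index pairs; the likelihood-ratio
    statistic 2*(ll_full - ll_reduced) is referred to a chi-square with
    df = k_full - k_reduced.  REML fits with different fixed structures are
    refused (their restricted likelihoods are not comparable).
    """
    if len({r.n_obs for r in results}) != 1:
        raise ValueError("models must be fitted to the same data (n_obs differ)")
    names = list(names) if names is not None else [r.method for r in results]
    table = pd.DataFrame(
        {
            "model": names,
            "method": [r.method for r in results],
            "k": [r.k for r in results],
            "loglik": [r.loglik for r in results],
            "aic": [r.aic for r in results],
            "bic": [r.bic for r in results],
        }
    )
    lrt = None
    if nested:
        rows = []
        for (i0, i1) in nested:
            r0, r1 = results[i0], results[i1]
            if ("REML" in r0.method or "REML" in r1.method) and (
                r0.params.active != r1.params.active
            ):
                raise ValueError(
                    "refusing a likelihood-ratio test between REML fits with "
                    "different fixed-effect structures; refit by ML"
                )
            df = r1.k - r0.k
            stat = max(2.0 * (r1.loglik - r0.loglik), 0.0)
            pval = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
            if df == 0 and stat > 0:
                pval = float("nan")
            rows.append({"reduced": names[i0], "full": names[i1],
                         "stat": stat, "df": df, "pvalue": pval})
        lrt = pd.DataFrame(rows)
    return table, lrt


def screen_active(result: FitResult, z: float = 1.96) -> tuple[str, ...]:
    """Active names whose |estimate / SE| reaches ``z`` (a0 always retained).

    Supports the model-reduction rule: refit after dropping coefficients
    that are not significant at the corresponding confidence level.
    """
    keep = []
    for n in result.params.active:
        est, se = getattr(result.params, n), result.se.get(n, np.inf)
        if n == "a0" or (se > 0 and abs(est / se) >= z):
            keep.append(n)
    return tuple(keep)
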