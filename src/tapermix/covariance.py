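"""Variance and correlation structures for the two-level taper model.

Residual model.  Within a tree the errors are Gaussian with standard
deviation proportional to a power of the tree's DBH,

    sd(eps) = sigma * g,   g = d**delta,

i.e. ``Var(eps) = sigma^2 * d**(2*delta)`` — the usual power-of-covariate
variance function on the SD scale.  Unequally spaced sections along a stem
may in addition be serially correlated; the continuous AR(1) structure
uses the height separation in metres:

    corr(eps_k, eps_k') = phi ** |h_k - h_k'|,   0 <= phi < 1.

Random effects.  A chosen subset of coefficients (``RandomSpec.expanded``)
carries additive random effects at plot and at tree-within-plot level,
``b_i ~ N(0, D_p)`` and ``b_ij ~ N(0, D_t)``, independent across levels and
subjects.  This module also assembles the block system (D, Z, R, residual)
used by the EBLUP calibration update and by the linearised fitting steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import TreeRecord
from .exceptions import ConfigurationError, ValidationError
from .taper import FixedParams, PARAM_NAMES, _coef_arrays, _eval_profile, diameter_gradient

__all__ = [
    "RandomSpec",
    "VarComp",
    "TaperMixedModel",
    "variance_weights",
    "car1_matrix",
    "assemble_calibration_system",
    "log_cholesky",
    "inv_log_cholesky",
]


@dataclass(frozen=True)
class RandomSpec:
    """Which coefficients carry random effects (same set at plot and tree level)."""

    expanded: tuple[str, ...]

    def __post_init__(self):
        exp = tuple(self.expanded)
        unknown = set(exp) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown expanded parameter(s): {sorted(unknown)}")
        if not 1 <= len(exp) <= len(PARAM_NAMES):
            raise ConfigurationError("expanded set must contain 1..9 parameter names")
        if len(set(exp)) != len(exp):
            raise ConfigurationError("expanded parameter names must be unique")
        object.__setattr__(self, "expanded", tuple(n for n in PARAM_NAMES if n in exp))

    @property
    def n_r(self) -> int:
        return len(self.expanded)


def _check_cov(m: np.ndarray, name: str, n_r: int) -> np.ndarray:
    m = np.asarray(m, float)
    if m.shape != (n_r, n_r):
        raise ValidationError(f"{name} must be {n_r}x{n_r}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValidationError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(m)
    if eig.min() < -1e-10 * max(1.0, abs(eig).max()):
        raise ValidationError(f"{name} must be positive semidefinite (eigs {eig})")
    return m


@dataclass(frozen=True)
class VarComp:
    """Estimated variance components of a fitted model.

    ``D_p``/``D_t`` are the plot- and tree-level random-effect covariance
    matrices (ordered as ``RandomSpec.expanded``); ``sigma2`` the residual
    scale; ``delta`` the DBH-power exponent of the SD-scale variance
    function; ``phi`` the CAR(1) coefficient (``None`` = independent
    residuals).  For fixed-effects fits ``D_p``/``D_t`` may be ``None``.
    """

    sigma2: float
    D_p: np.ndarray | None = None
    D_t: np.ndarray | None = None
    delta: float = 0.0
    phi: float | None = None

    def __post_init__(self):
        if not self.sigma2 > 0:
            raise ValidationError(f"sigma2 must be > 0, got {self.sigma2}")
        if (self.D_p is None) != (self.D_t is None):
            raise ValidationError("D_p and D_t must be given together")
        if self.D_p is not None:
            n_r = np.asarray(self.D_p).shape[0]
            object.__setattr__(self, "D_p", _check_cov(self.D_p, "D_p", n_r))
            object.__setattr__(self, "D_t", _check_cov(self.D_t, "D_t", n_r))
        if self.phi is not None and not (0.0 <= self.phi < 1.0):
            raise ValidationError(f"phi must lie in [0, 1), got {self.phi}")


@dataclass(frozen=True)
class TaperMixedModel:
    """A self-contained mixed taper model: coefficients + random structure."""

    params: FixedParams
    spec: RandomSpec
    varcomp: VarComp

    def __post_init__(self):
        if self.varcomp.D_p is None:
            raise ConfigurationError("TaperMixedModel requires plot/tree covariance matrices")
        if set(self.spec.expanded) - set(self.params.active):
            raise ConfigurationError("expanded parameters must be active")
        if self.varcomp.D_p.shape[0] != self.spec.n_r:
            raise ConfigurationError("covariance dimension does not match the expanded set")


def variance_weights(d, delta: float):
    """SD-scale variance-function weight ``g = d**delta`` per observation.

    The residual variance is ``sigma2 * g**2``; ``g = 1`` when ``delta = 0``.
    """
    d = np.asarray(d, float)
    if np.any(d <= 0):
        raise ValueError("DBH must be > 0")
    out = d**delta
    return float(out) if out.ndim == 0 else out


def car1_matrix(heights, phi: float) -> np.ndarray:
    """CAR(1) correlation matrix: entry (k, k') = phi ** |h_k - h_k'| (m)."""
    if not (0.0 <= phi < 1.0):
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    h = np.asarray(heights, float)
    dist = np.abs(h[:, None] - h[None, :])
    if phi == 0.0:
        return np.eye(len(h))
    return phi**dist


def _tree_error_cov(tree: TreeRecord, vc: VarComp) -> np.ndarray:
    """R block for one tree: sigma2 * g^2 * M with M identity or CAR(1)."""
    g = variance_weights(tree.d, vc.delta)
    n = len(tree.sections)
    if vc.phi is None:
        M = np.eye(n)
    else:
        M = car1_matrix(tree.section_heights, vc.phi)
    return vc.sigma2 * g**2 * M


def assemble_calibration_system(
    model: TaperMixedModel,
    plot_trees: Sequence[TreeRecord],
    current_effects: np.ndarray | None = None,
):
    """Assemble (D, Z, R, residual) for one plot's calibration observations.

    ``plot_trees`` carry their calibration observations as ``sections``.
    The joint effect vector is ordered ``[b_plot, b_tree1, b_tree2, ...]``,
    each block ordered as ``spec.expanded``; ``current_effects`` is that
    stacked vector (zeros when omitted).  Z holds the derivative of the
    profile w.r.t. each expanded coefficient, evaluated at the current
    effects; the plot-effect columns repeat the tree-effect entries for
    every row (the derivative is the same at both levels), and tree blocks
    lie on the block diagonal.  The residual is ``y - f(beta, b)``.
    """
    spec, vc, params = model.spec, model.varcomp, model.params
    n_r = spec.n_r
    n_t = len(plot_trees)
    if n_t == 0:
        raise ValidationError("at least one tree is required")
    n_obs = sum(len(t.sections) for t in plot_trees)
    dim = n_r * (1 + n_t)
    b = np.zeros(dim) if current_effects is None else np.asarray(current_effects, float)
    if b.shape != (dim,):
        raise ValidationError(f"current_effects must have length {dim}, got {b.shape}")

    D = np.zeros((dim, dim))
    D[:n_r, :n_r] = vc.D_p
    Z = np.zeros((n_obs, dim))
    R = np.zeros((n_obs, n_obs))
    resid = np.zeros(n_obs)

    row = 0
    for j, tree in enumerate(plot_trees):
        for s in tree.sections:
            if s.h_i > tree.h:
                raise ValidationError(
                    f"calibration height {s.h_i} exceeds tree height {tree.h}"
                )
        nj = len(tree.sections)
        sl = slice(row, row + nj)
        c0, c1 = n_r * (1 + j), n_r * (2 + j)
        D[c0:c1, c0:c1] = vc.D_t
        eff = dict(zip(spec.expanded, b[:n_r] + b[c0:c1]))
        grad = diameter_gradient(
            params, eff, tree.d, tree.h, tree.section_heights, wrt=spec.expanded
        ).reshape(nj, n_r)
        Z[sl, :n_r] = grad
        Z[sl, c0:c1] = grad
        R[sl, sl] = _tree_error_cov(tree, vc)
        c = _coef_arrays(params, eff)
        pred = _eval_profile(tree.d, tree.h, tree.section_heights, c, warn=False)
        resid[sl] = tree.section_diameters - pred
        row += nj
    if row != n_obs:
        raise ValidationError("internal consistency error: row count mismatch")
    return D, Z, R, resid


def log_cholesky(cov: np.ndarray, jitter: float = 0.0) -> np.ndarray:
    """Unconstrained log-Cholesky parameters of a PSD matrix.

    Lower-triangular Cholesky factor with logged diagonal, packed row-wise.
    Inverse of :func:`inv_log_cholesky`; unique for positive-definite input.
    """
    cov = np.asarray(cov, float)
    n = cov.shape[0]
    L = np.linalg.cholesky(cov + (jitter if jitter else 1e-300) * np.eye(n))
    out = []
    for i in range(n):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def inv_log_cholesky(theta: np.ndarray, n: int) -> np.ndarray:
    """Rebuild the PSD matrix from packed log-Cholesky parameters."""
    L = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L @ L.T
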