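"""The variable-exponent stem taper equation and derived quantities.

The profile model predicts over-bark diameter ``d_i`` (cm) at height
``h_i`` (m) on a stem of DBH ``d`` (cm) and total height ``h`` (m):

    d_i = a0 * d**a1 * h**a2 * x**B
    B   = b1*q**4 + b2*exp(-d/h) + b3*x**0.1 + b4/d + b5*h**w + b6*x

with the relative-position terms

    q = h_i / h,   w = 1 - q**(1/3),   x = w / (1 - (1.3/h)**(1/3)).

``x`` equals 1 exactly at breast height (h_i = 1.3 m) — the curve is pinned
near the measured DBH there — and 0 at the tip, where the predicted
diameter is 0 by convention.  The variable exponent ``B`` lets a single
smooth curve render the neiloid butt, paraboloid mid-stem and conic top.

Subject-level behaviour enters by adding *effects* (random-effect
predictions) to individual coefficients; every routine here accepts an
optional mapping ``{parameter name: offset}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, optimize

from .exceptions import ConfigurationError

__all__ = [
    "PARAM_NAMES",
    "FixedParams",
    "EffectVector",
    "BELOW_PROFILE",
    "relative_terms",
    "predict_diameter",
    "diameter_gradient",
    "stem_volume",
    "merchantable_height",
]

#: Canonical coefficient order used everywhere (arrays, gradients, reports).
PARAM_NAMES: tuple[str, ...] = ("a0", "a1", "a2", "b1", "b2", "b3", "b4", "b5", "b6")

#: Additive offsets to named coefficients (a subject's random effects).
EffectVector = Mapping[str, float]

#: Sentinel returned by :func:`merchantable_height` when the requested top
#: diameter exceeds the profile everywhere (the log would lie "below" the stump).
BELOW_PROFILE = None


@dataclass(frozen=True)
class FixedParams:
    """The nine fixed coefficients; ``active`` lists those in the model.

    Inactive coefficients are pinned to exactly 0 and excluded from
    estimation.  Defaults are the conventional starting point for the
    nonlinear fits (a0 = 1, a1 = 1, a2 = 0, b1..b6 = 0.1).
    """

    a0: float = 1.0
    a1: float = 1.0
    a2: float = 0.0
    b1: float = 0.1
    b2: float = 0.1
    b3: float = 0.1
    b4: float = 0.1
    b5: float = 0.1
    b6: float = 0.1
    active: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self):
        unknown = set(self.active) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")
        object.__setattr__(self, "active", tuple(n for n in PARAM_NAMES if n in self.active))
        if "a0" not in self.active or not self.a0 > 0:
            raise ConfigurationError("a0 must be active and > 0")
        for n in PARAM_NAMES:
            if n not in self.active and getattr(self, n) != 0.0:
                object.__setattr__(self, n, 0.0)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = self.active if names is None else names
        return np.array([getattr(self, n) for n in names], float)

    def with_values(self, names: Sequence[str], values: Sequence[float]) -> "FixedParams":
        return replace(self, **dict(zip(names, (float(v) for v in values))))


def _check_effects(params: FixedParams, effects: EffectVector | None) -> dict[str, float]:
    if not effects:
        return {}
    bad = set(effects) - set(params.active)
    if bad:
        raise ConfigurationError(
            f"effects on inactive/unknown parameter(s): {sorted(bad)}"
        )
    return dict(effects)


def relative_terms(h_i, h):
    """Return the relative-position terms ``(q, w, x)``.

    ``h`` must exceed breast height (1.3 m); ``h_i`` must lie in [0, h].
    """
    h_i = np.asarray(h_i, float)
    h = np.asarray(h, float)
    if np.any(h <= 1.3):
        raise ValueError("total height must exceed breast height (1.3 m)")
    if np.any((h_i < 0) | (h_i > h)):
        raise ValueError("section height must lie in [0, h]")
    q = h_i / h
    w = 1.0 - np.cbrt(q)
    x = w / (1.0 - np.cbrt(1.3 / h))
    if q.ndim == 0:
        return float(q), float(w), float(x)
    return q, w, x


def _coef_arrays(params: FixedParams, effects: EffectVector | None):
    eff = _check_effects(params, effects)
    return {n: getattr(params, n) + eff.get(n, 0.0) for n in PARAM_NAMES}


def _eval_profile(d, h, h_i, c: Mapping[str, object], warn: bool = True):
    """Vectorised profile evaluation; ``c`` maps names to broadcastable values."""
    d = np.asarray(d, float)
    h = np.asarray(h, float)
    h_i = np.asarray(h_i, float)
    q = h_i / h
    w = 1.0 - np.cbrt(q)
    x = w / (1.0 - np.cbrt(1.3 / h))
    expo = (
        c["b1"] * q**4
        + c["b2"] * np.exp(-d / h)
        + c["b3"] * x**0.1
        + c["b4"] / d
        + c["b5"] * h**w
        + c["b6"] * x
    )
    tip = x <= 0.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        xb = np.where(tip, 0.0, np.power(np.where(tip, 1.0, x), expo))
    if warn and np.any(tip & (np.asarray(expo) <= 0.0)):
        warnings.warn(
            "profile evaluated at the tip with a non-positive exponent; "
            "returning the limit value 0",
            RuntimeWarning,
            stacklevel=3,
        )
    out = c["a0"] * d ** c["a1"] * h ** c["a2"] * xb
    return np.where(tip, 0.0, out)


def predict_diameter(
    params: FixedParams,
    effects: EffectVector | None,
    d,
    h,
    h_i,
):
    """Predicted over-bark diameter (cm) at height(s) ``h_i``.

    ``effects`` shifts the named coefficients additively (subject-specific
    prediction); pass ``None`` or ``{}`` for the mean response.  Returns a
    scalar for scalar ``h_i``, else an array.  ``d_i(h) = 0`` by convention.
    """
    np.asarray(h_i, float)
    relative_terms(h_i, h)  # domain checks
    if np.any(np.asarray(d, float) <= 0):
        raise ValueError("DBH must be > 0")
    c = _coef_arrays(params, effects)
    out = _eval_profile(d, h, h_i, c)
    if out.ndim == 0:
        return float(out)
    return out


def diameter_gradient(
    params: FixedParams,
    effects: EffectVector | None,
    d,
    h,
    h_i,
    wrt: Sequence[str],
):
    """Partial derivatives of the predicted diameter w.r.t. coefficients.

    Central finite differences with step ``max(1e-6, 1e-6 * |theta|)``.
    Because random effects enter the coefficient vector linearly, these are
    also the derivatives with respect to the effects — the entries of the
    calibration design matrix Z.  Returns shape ``(..., len(wrt))``.
    """
    bad = [n for n in wrt if n not in params.active]
    if bad:
        raise ConfigurationError(f"gradient requested for inactive parameter(s): {bad}")
    eff = _check_effects(params, effects)
    relative_terms(h_i, h)
    base = {n: getattr(params, n) + eff.get(n, 0.0) for n in PARAM_NAMES}
    cols = []
    for name in wrt:
        theta = base[name]
        step = max(1e-6, 1e-6 * abs(theta))
        up = dict(base, **{name: theta + step})
        dn = dict(base, **{name: theta - step})
        hi_arr = _eval_profile(d, h, h_i, up, warn=False)
        lo_arr = _eval_profile(d, h, h_i, dn, warn=False)
        cols.append((hi_arr - lo_arr) / (2.0 * step))
    return np.stack(cols, axis=-1)


def stem_volume(
    params: FixedParams,
    effects: EffectVector | None,
    d,
    h,
    lower: float = 0.0,
    upper: float | None = None,
    abs_tol: float = 1e-8,
) -> float:
    """Stem volume (m^3) between two heights by adaptive quadrature.

    Integrates ``pi * (d_i(t)/200)**2 dt`` to absolute tolerance ``abs_tol``
    (default 1e-8 m^3, far below the 4-significant-figure volumes of
    practical interest).
    """
    upper = float(h) if upper is None else float(upper)
    lower = float(lower)
    if not (0.0 <= lower < upper <= float(h) + 1e-12):
        raise ValueError(f"integration bounds [{lower}, {upper}] outside [0, {h}]")
    c = _coef_arrays(params, effects)

    def integrand(t):
        di = _eval_profile(d, h, t, c, warn=False)
        return np.pi * (di / 200.0) ** 2

    val, _ = integrate.quad(integrand, lower, upper, epsabs=abs_tol, epsrel=1e-10, limit=200)
    return float(val)


def merchantable_height(
    params: FixedParams,
    effects: EffectVector | None,
    d,
    h,
    top_diameter: float,
):
    """Largest height (m) in [1.3, h] where the profile equals ``top_diameter``.

    The profile has no closed-form inverse, so the upper, monotone-decreasing
    segment is bracketed on a fine grid and refined by root finding to
    ``|d_i - top| < 1e-6`` cm.  Returns :data:`BELOW_PROFILE` (``None``) when
    the requested top diameter exceeds the profile everywhere.
    """
    if not top_diameter > 0:
        raise ValueError("top_diameter must be > 0")
    c = _coef_arrays(params, effects)
    hs = np.linspace(1.3, float(h), 1024)
    di = _eval_profile(d, h, hs, c, warn=False)
    above = np.nonzero(di >= top_diameter)[0]
    if len(above) == 0:
        return BELOW_PROFILE
    k = above[-1]
    if k == len(hs) - 1:  # profile still above the limit at the tip grid point
        return float(h)
    f = lambda t: float(_eval_profile(d, h, t, c, warn=False)) - top_diameter
    root = optimize.brentq(f, hs[k], hs[k + 1], xtol=1e-10)
    return float(root)
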