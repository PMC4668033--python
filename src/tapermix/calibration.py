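"""Multilevel EBLUP calibration: localize a fitted mixed taper model to new
subjects from one or more extra stem-diameter measurements.

For a new plot with trees carrying calibration observations y, the joint
plot/tree random-effect prediction solves the fixed point

    b = D Z' (Z D Z' + R)^{-1} [ y - f(beta, b) + Z b ]

where Z is the derivative of the profile w.r.t. the expanded coefficients
evaluated at the current b (re-evaluated every pass, consistent with FOCE
fitting), D = blockdiag(D_p, D_t, ..., D_t) and R the residual covariance.
By the Woodbury identity this fixed point is exactly the stationary point
of the penalized criterion  ||y - f(b)||^2_{R^-1} + b' D^{-1} b,  i.e. the
(approximate) posterior mode of the random effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .covariance import TaperMixedModel, assemble_calibration_system
from .data_io import TaperDataset, TreeRecord, observed_stem_volume
from .exceptions import ConfigurationError, ValidationError
from .taper import predict_diameter, stem_volume

__all__ = [
    "CalibrationResult",
    "calibrate",
    "subject_specific_predict",
    "calibration_height_sweep",
    "SweepResult",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Predicted random effects for one (new) plot and its trees."""

    plot_effects: dict[str, float]
    tree_effects: dict[str, dict[str, float]]
    iterations: int
    converged: bool
    max_abs_update: float


def _as_mixed_model(model) -> TaperMixedModel:
    if isinstance(model, TaperMixedModel):
        return model
    if hasattr(model, "mixed_model"):
        return model.mixed_model()
    raise ConfigurationError(
        "model must be a TaperMixedModel or a mixed-effects FitResult"
    )


def calibrate(
    model,
    plot_trees: Sequence[TreeRecord],
    tol: float = 1e-8,
    max_iter: int = 100,
    reeval_z: bool = True,
    raise_on_fail: bool = False,
) -> CalibrationResult:
    """Predict plot- and tree-level random effects from calibration sections.

    ``plot_trees`` belong to one plot; each tree's ``sections`` are its
    calibration observations.  Starting from b = 0 the update is iterated
    until the maximum absolute change drops below ``tol`` (default 1e-8) or
    ``max_iter`` passes.  ``reeval_z=False`` freezes the linearization at
    the first pass (single-linearization variant).
    """
    mm = _as_mixed_model(model)
    n_r = mm.spec.n_r
    n_t = len(plot_trees)
    dim = n_r * (1 + n_t)
    b = np.zeros(dim)
    frozen = None
    it = 0
    delta = np.inf
    for it in range(1, max_iter + 1):
        if frozen is None or reeval_z:
            D, Z, R, resid = assemble_calibration_system(mm, plot_trees, b)
            if not reeval_z:
                frozen = (D, Z, R)
        else:
            D, Z, R = frozen
            _, _, _, resid = assemble_calibration_system(mm, plot_trees, b)
        S = Z @ D @ Z.T + R
        cf = cho_factor(S, lower=True)
        rhs = resid + Z @ b
        b_new = D @ Z.T @ cho_solve(cf, rhs)
        delta = float(np.max(np.abs(b_new - b)))
        b = b_new
        if delta < tol:
            break
    converged = delta < tol
    if not converged and raise_on_fail:
        raise ValidationError(f"calibration did not converge in {max_iter} iterations")
    names = mm.spec.expanded
    plot_eff = dict(zip(names, b[:n_r].tolist()))
    tree_eff = {
        t.tree_id: dict(zip(names, b[n_r * (1 + j): n_r * (2 + j)].tolist()))
        for j, t in enumerate(plot_trees)
    }
    return CalibrationResult(
        plot_effects=plot_eff,
        tree_effects=tree_eff,
        iterations=it,
        converged=converged,
        max_abs_update=delta,
    )


def subject_specific_predict(
    model,
    calib: CalibrationResult,
    tree: TreeRecord,
    h_i,
    level: str = "tree",
):
    """Subject-specific diameter predictions on a height grid.

    ``level="plot"`` adds the plot effect only; ``level="tree"`` adds plot
    plus the tree's effect (the tree must appear in ``calib``).
    """
    mm = _as_mixed_model(model)
    if level not in {"plot", "tree"}:
        raise ConfigurationError("level must be 'plot' or 'tree'")
    eff = dict(calib.plot_effects)
    if level == "tree":
        if tree.tree_id not in calib.tree_effects:
            raise KeyError(f"tree '{tree.tree_id}' was not calibrated")
        for k, v in calib.tree_effects[tree.tree_id].items():
            eff[k] = eff.get(k, 0.0) + v
    return predict_diameter(mm.params, eff, tree.d, tree.h, h_i)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a one-section-per-tree calibration sweep."""

    table: pd.DataFrame  # one row per calibration relative-height class
    overall: dict[str, float]  # pooled RMSEs: mean / plot / tree responses


def calibration_height_sweep(
    model,
    eval_data: TaperDataset,
    bin_edges: np.ndarray | None = None,
    volumes: bool = True,
    volume_tol: float = 1e-7,
) -> SweepResult:
    """Leave-one-section-in calibration sweep over an evaluation dataset.

    For every tree and every measured section, the model is calibrated on
    that single section (tree treated as the only tree of a new plot) and
    the remaining sections — plus, optionally, total stem volume — are
    predicted subject-specifically.  Errors are pooled into relative-height
    classes of the calibrating section (default width 0.1).  Classes with
    no calibrating sections are reported with ``n = 0`` and NaN statistics.

    ``overall`` pools diameter RMSE across all calibrations for the mean
    response and for plot-level and tree-level subject-specific responses.
    """
    mm = _as_mixed_model(model)
    edges = np.arange(0.0, 1.0 + 1e-9, 0.1) if bin_edges is None else np.asarray(bin_edges, float)
    nbin = len(edges) - 1
    err_d: list[list[float]] = [[] for _ in range(nbin)]
    err_v: list[list[float]] = [[] for _ in range(nbin)]
    obs_d: list[list[float]] = [[] for _ in range(nbin)]
    obs_v: list[list[float]] = [[] for _ in range(nbin)]
    pooled = {"mean": [], "plot": [], "tree": []}

    for t in eval_data:
        if len(t.sections) < 2:
            raise ValidationError(
                f"tree {t.key} has fewer than 2 sections (nothing left to score)"
            )
        hs = t.section_heights
        ds = t.section_diameters
        v_obs = observed_stem_volume(t) if volumes else None
        mean_pred = predict_diameter(mm.params, None, t.d, t.h, hs)
        for k in range(len(hs)):
            rel = hs[k] / t.h
            ib = min(int(np.searchsorted(edges, rel, side="right")) - 1, nbin - 1)
            ib = max(ib, 0)
            cal_tree = t.with_sections([t.sections[k]])
            cal = calibrate(mm, [cal_tree])
            rest = np.arange(len(hs)) != k
            ss_tree = subject_specific_predict(mm, cal, t, hs[rest], level="tree")
            ss_plot = subject_specific_predict(mm, cal, t, hs[rest], level="plot")
            e = ds[rest] - ss_tree
            err_d[ib].extend(e.tolist())
            obs_d[ib].extend(ds[rest].tolist())
            pooled["mean"].extend((ds[rest] - mean_pred[rest]).tolist())
            pooled["plot"].extend((ds[rest] - ss_plot).tolist())
            pooled["tree"].extend(e.tolist())
            if volumes:
                eff = dict(cal.plot_effects)
                for kk, vv in cal.tree_effects[t.tree_id].items():
                    eff[kk] = eff.get(kk, 0.0) + vv
                v_pred = stem_volume(mm.params, eff, t.d, t.h,
                                     lower=hs[0], upper=t.h, abs_tol=volume_tol)
                err_v[ib].append(v_obs - v_pred)
                obs_v[ib].append(v_obs)

    rows = []
    for ib in range(nbin):
        ed, ov = np.array(err_d[ib]), np.array(err_v[ib])
        od = np.array(obs_d[ib])
        row = {
            "class_low": edges[ib],
            "class_high": edges[ib + 1],
            "n_d": len(ed),
            "rmse_d": float(np.sqrt(np.mean(ed**2))) if len(ed) else np.nan,
            "mpe_pct_d": (100.0 * ed.mean() / od.mean()) if len(ed) else np.nan,
            "n_v": len(ov),
            "rmse_v": float(np.sqrt(np.mean(ov**2))) if len(ov) else np.nan,
            "mpe_pct_v": (100.0 * ov.mean() / np.mean(obs_v[ib])) if len(ov) else np.nan,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    overall = {
        f"rmse_d_{k}": float(np.sqrt(np.mean(np.array(v) ** 2)))
        for k, v in pooled.items()
    }
    return SweepResult(table=table, overall=overall)
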