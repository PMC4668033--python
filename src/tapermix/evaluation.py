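"""Model responses (mean, population-averaged, subject-specific) and the
evaluation statistics RMSE and percentage mean prediction error, with
disaggregation by grouping classes.

RMSE uses the degrees-of-freedom-corrected form

    RMSE = sqrt( sum (y - yhat)^2 / (n - p) )

where ``p`` defaults to 0 and is conventionally set to the number of fixed
coefficients when a single pooled statistic for a fitted model is wanted.
The percentage mean prediction error is 100 * mean(y - yhat) / mean(y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .covariance import TaperMixedModel
from .data_io import TaperDataset
from .exceptions import ValidationError
from .taper import FixedParams, predict_diameter

__all__ = [
    "rmse",
    "mean_prediction_error_pct",
    "mean_response",
    "pa_response",
    "disaggregate",
    "EvalReport",
]


def rmse(observed, predicted, p: int = 0) -> float:
    """Root mean square error with an (n - p) denominator."""
    y = np.asarray(observed, float)
    yh = np.asarray(predicted, float)
    if y.shape != yh.shape:
        raise ValidationError("observed and predicted must have equal length")
    n = y.size
    if n <= p:
        raise ValidationError(f"need n > p, got n={n}, p={p}")
    return float(np.sqrt(np.sum((y - yh) ** 2) / (n - p)))


def mean_prediction_error_pct(observed, predicted) -> float:
    """Percentage mean prediction error: 100 * mean(y - yhat) / mean(y)."""
    y = np.asarray(observed, float)
    yh = np.asarray(predicted, float)
    if y.shape != yh.shape:
        raise ValidationError("observed and predicted must have equal length")
    ybar = y.mean()
    if ybar == 0:
        raise ValidationError("mean of observations is zero; relative error undefined")
    return float(100.0 * np.mean(y - yh) / ybar)


def _section_frame(data: TaperDataset) -> pd.DataFrame:
    rows = [
        {"plot": t.plot_id, "tree": t.tree_id, "d": t.d, "h": t.h,
         "h_i": s.h_i, "d_i": s.d_i}
        for t in data
        for s in t.sections
    ]
    return pd.DataFrame(rows)


def mean_response(params_or_model, data: TaperDataset) -> pd.DataFrame:
    """Fixed-coefficients-only predictions for every section of a dataset.

    Accepts a :class:`FixedParams` or any model object exposing ``params``.
    Returns a tidy frame with observed ``d_i`` and predicted ``pred``.
    """
    params = params_or_model if isinstance(params_or_model, FixedParams) \
        else params_or_model.params
    df = _section_frame(data)
    df["pred"] = predict_diameter(
        params, None, df["d"].to_numpy(), df["h"].to_numpy(), df["h_i"].to_numpy()
    )
    return df


def pa_response(model, data: TaperDataset, n_draws: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Population-averaged predictions by Monte Carlo over the random effects.

    Draws ``n_draws`` plot- and tree-level effect vectors from N(0, D_p) and
    N(0, D_t), evaluates the subject-specific profile for each draw and
    averages.  One shared set of draws is used for all sections (fixed
    ``seed``), so the estimate is smooth along the stem.
    """
    if not isinstance(model, TaperMixedModel):
        model = model.mixed_model()
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    vc, spec, params = model.varcomp, model.spec, model.params
    df = _section_frame(data)
    d = df["d"].to_numpy()
    h = df["h"].to_numpy()
    hi = df["h_i"].to_numpy()
    if not np.any(vc.D_p) and not np.any(vc.D_t):
        # degenerate effects distribution: PA coincides with M exactly
        df["pred"] = predict_diameter(params, None, d, h, hi)
        return df
    rng = np.random.default_rng(seed)
    n_r = spec.n_r
    draws = rng.multivariate_normal(np.zeros(n_r), vc.D_p, size=n_draws) + \
        rng.multivariate_normal(np.zeros(n_r), vc.D_t, size=n_draws)
    acc = np.zeros(len(df))
    for b in draws:
        acc += predict_diameter(params, dict(zip(spec.expanded, b)), d, h, hi)
    df["pred"] = acc / n_draws
    return df


@dataclass(frozen=True)
class EvalReport:
    """Per-group evaluation table (one row per class, NaN where empty)."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def disaggregate(
    observed,
    predicted,
    groups,
    categories: Sequence | None = None,
    p: int = 0,
) -> EvalReport:
    """Per-class RMSE and percentage mean prediction error.

    ``groups`` labels each observation (e.g. a relative-height class).
    ``categories`` optionally fixes the full set of classes so that empty
    ones appear as missing (n = 0, NaN statistics) rather than silently
    vanishing.  ``p`` is apportioned to every class as given (default 0).
    """
    y = np.asarray(observed, float)
    yh = np.asarray(predicted, float)
    g = pd.Series(groups)
    if not (len(y) == len(yh) == len(g)):
        raise ValidationError("observed, predicted and groups must align")
    cats = list(categories) if categories is not None else sorted(g.unique())
    rows = []
    for cat in cats:
        mask = (g == cat).to_numpy()
        n = int(mask.sum())
        if n > p and n > 0:
            rows.append({
                "group": cat, "n": n,
                "rmse": rmse(y[mask], yh[mask], p=p),
                "mpe_pct": mean_prediction_error_pct(y[mask], yh[mask]),
            })
        else:
            rows.append({"group": cat, "n": n, "rmse": np.nan, "mpe_pct": np.nan})
    return EvalReport(table=pd.DataFrame(rows))


def relative_height_classes(h_i, h, width: float = 0.1):
    """Bin relative heights h_i / h into classes of the given width.

    Returns integer class labels ``0..ceil(1/width)-1`` (the top class is
    closed so that h_i = h falls in the last bin).
    """
    rel = np.asarray(h_i, float) / np.asarray(h, float)
    nbin = int(np.ceil(1.0 / width))
    lab = np.minimum((rel / width).astype(int), nbin - 1)
    return lab
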