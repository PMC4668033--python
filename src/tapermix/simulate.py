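"""Synthetic hierarchical taper data with the exact statistical structure
the analysis assumes, plus the parameter-recovery harness.

The generator emulates the study design behind the packaged coefficient
sets: ~70 plots of 6 felled trees each, unequally spaced stem sections
(a stump cut near the ground, then logs), two-level bivariate random
effects, power-of-DBH heteroscedasticity and optional within-tree CAR(1)
correlation.  Defaults reproduce the published data summary: DBH lognormal
with mean 23.5 cm and SD 10.2 cm on the 6.5-56.9 cm range, heights from a
DBH-height allometry spanning roughly 4-29 m, stump heights uniform on
0.03-0.40 m and log lengths up to 2.5 m (shorter logs on shorter stems, so
per-tree section counts land in the observed 7-24 range).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .coeffs import load_coefficient_set
from .covariance import RandomSpec, VarComp, car1_matrix, variance_weights
from .data_io import SectionObs, TaperDataset, TreeRecord
from .exceptions import ConfigurationError, ConvergenceError
from .taper import FixedParams, _coef_arrays, _eval_profile

__all__ = ["GeneratorConfig", "generate", "recovery_experiment", "default_mixed_config"]


def _published_mm3():
    cs = load_coefficient_set("asturias-mm3")
    return cs.params, cs.spec, cs.varcomp


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the hierarchical taper-data generator.

    The generating model defaults to the packaged mixed coefficient set
    (random effects on a1 and b3 at plot and tree level, SD-scale power
    variance, no serial correlation).  ``height_alpha``/``height_gamma``
    define the DBH-height allometry  h = 1.3 + alpha * d**gamma  with
    lognormal multiplicative noise of coefficient ``height_cv``.  Log
    lengths are uniform on (0.3, min(2.5, max(0.5, h/8))) m.  Optional
    measurement rounding mimics the field protocol (d_i to 0.1 cm, h_i to
    0.01 m); it is off by default so that recovery studies see the model's
    exact error law.
    """

    n_plots: int = 70
    trees_per_plot: int = 6
    seed: int = 0
    params: FixedParams = field(default_factory=lambda: _published_mm3()[0])
    spec: RandomSpec = field(default_factory=lambda: _published_mm3()[1])
    varcomp: VarComp = field(default_factory=lambda: _published_mm3()[2])
    dbh_mean: float = 23.5
    dbh_sd: float = 10.2
    dbh_range: tuple[float, float] = (6.5, 56.9)
    height_alpha: float = 1.4
    height_gamma: float = 0.7
    height_cv: float = 0.08
    height_max: float = 29.5
    stump_range: tuple[float, float] = (0.03, 0.40)
    log_length_max: float = 2.5
    log_length_min: float = 0.3
    round_measurements: bool = False

    def __post_init__(self):
        if self.n_plots < 1 or self.trees_per_plot < 1:
            raise ConfigurationError("counts must be positive")
        if self.varcomp.D_p is None:
            raise ConfigurationError("generator needs plot/tree covariance matrices")


def default_mixed_config(**overrides) -> GeneratorConfig:
    """The study-condition generator config (published mixed model, 70x6)."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


@dataclass(frozen=True)
class GeneratedTruth:
    """True subject effects behind one generated dataset."""

    plot_effects: dict[str, np.ndarray]
    tree_effects: dict[tuple[str, str], np.ndarray]
    n_truncated: int

    def to_frame(self, expanded: Sequence[str]) -> pd.DataFrame:
        rows = [
            {"level": "plot", "plot": p, "tree": "",
             **dict(zip(expanded, v))}
            for p, v in self.plot_effects.items()
        ] + [
            {"level": "tree", "plot": p, "tree": t, **dict(zip(expanded, v))}
            for (p, t), v in self.tree_effects.items()
        ]
        return pd.DataFrame(rows)


def _draw_tree_size(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[float, float]:
    cv2 = (cfg.dbh_sd / cfg.dbh_mean) ** 2
    sig = np.sqrt(np.log1p(cv2))
    mu = np.log(cfg.dbh_mean) - 0.5 * sig**2
    for _ in range(200):
        d = float(rng.lognormal(mu, sig))
        if not (cfg.dbh_range[0] <= d <= cfg.dbh_range[1]):
            continue
        noise = float(rng.lognormal(0.0, cfg.height_cv))
        h = 1.3 + cfg.height_alpha * d**cfg.height_gamma * noise
        if 1.8 < h <= cfg.height_max:
            return d, h
    raise ConvergenceError("could not draw a feasible tree size in 200 attempts")


def _section_heights(cfg: GeneratorConfig, h: float, rng: np.random.Generator) -> np.ndarray:
    # per-tree log-length cap shrinks for short stems so that section counts
    # stay within the field protocol's observed 7-24 range
    top = min(cfg.log_length_max, max(0.5, h / 8.0))
    for _ in range(50):
        hs = [float(rng.uniform(*cfg.stump_range))]
        while True:
            step = float(rng.uniform(cfg.log_length_min, top))
            nxt = hs[-1] + step
            if nxt >= h - 0.05:
                break
            hs.append(nxt)
        if 7 <= len(hs) <= 24:
            return np.asarray(hs)
    return np.asarray(hs[:24])


def generate(config: GeneratorConfig) -> tuple[TaperDataset, GeneratedTruth]:
    """Simulate one hierarchical dataset; returns (dataset, true effects).

    Per plot i a plot effect b_i ~ N(0, D_p); per tree j a tree effect
    b_ij ~ N(0, D_t), a DBH and height, and a section schedule; then
    d_i = f(h_i; beta + b_i + b_ij) + eps with Var(eps) = sigma2 * d**(2 delta)
    and within-tree CAR(1) correlation when phi is set.  Negative simulated
    diameters are truncated at 0 and counted.  Byte-reproducible by seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    vc, spec, params = cfg.varcomp, cfg.spec, cfg.params
    n_r = spec.n_r
    trees: list[TreeRecord] = []
    plot_truth: dict[str, np.ndarray] = {}
    tree_truth: dict[tuple[str, str], np.ndarray] = {}
    n_trunc = 0
    width = len(str(cfg.n_plots))
    for i in range(cfg.n_plots):
        plot_id = f"P{i + 1:0{width}d}"
        b_i = rng.multivariate_normal(np.zeros(n_r), vc.D_p)
        plot_truth[plot_id] = b_i
        for j in range(cfg.trees_per_plot):
            tree_id = f"T{j + 1}"
            b_ij = rng.multivariate_normal(np.zeros(n_r), vc.D_t)
            tree_truth[(plot_id, tree_id)] = b_ij
            d, h = _draw_tree_size(cfg, rng)
            hs = _section_heights(cfg, h, rng)
            eff = dict(zip(spec.expanded, b_i + b_ij))
            c = _coef_arrays(params, eff)
            mean = _eval_profile(d, h, hs, c, warn=False)
            sd = np.sqrt(vc.sigma2) * variance_weights(d, vc.delta)
            if vc.phi is None:
                eps = rng.normal(0.0, sd, size=len(hs))
            else:
                M = car1_matrix(hs, vc.phi)
                eps = sd * rng.multivariate_normal(np.zeros(len(hs)), M)
            di = mean + eps
            n_trunc += int((di < 0).sum())
            di = np.maximum(di, 0.0)
            if cfg.round_measurements:
                di = np.round(di, 1)
                hs = np.round(hs, 2)
            secs = tuple(SectionObs(h_i=float(a), d_i=float(b)) for a, b in zip(hs, di))
            trees.append(TreeRecord(plot_id=plot_id, tree_id=tree_id,
                                    d=d, h=h, sections=secs, h_st=float(hs[0])))
    ds = TaperDataset(tuple(trees), provenance=f"synthetic(seed={cfg.seed})")
    return ds, GeneratedTruth(plot_truth, tree_truth, n_trunc)


def recovery_experiment(
    config: GeneratorConfig,
    n_replicates: int,
    criterion: str = "REML",
    variance: bool = True,
    car1: bool = False,
    active: Sequence[str] | None = None,
    max_outer: int = 200,
) -> pd.DataFrame:
    """Generate -> fit -> compare: bias, empirical SE and 95% coverage per
    fixed coefficient over replicate simulated datasets.

    Replicate r uses seed ``config.seed + r``.  Replicates whose fit fails
    to converge appear in the output with ``converged = False`` counts; they
    are reported, never silently dropped.
    """
    from .estimation import fit_foce  # local import to avoid a cycle
    from .taper import PARAM_NAMES

    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    names = tuple(active) if active is not None else config.params.active
    truth = {n: getattr(config.params, n) for n in names}
    est_rows, cover_rows = [], []
    failures = 0
    for r in range(n_replicates):
        cfg_r = replace(config, seed=int(config.seed) + r)
        data, _ = generate(cfg_r)
        try:
            fit = fit_foce(data, config.spec, active=names, criterion=criterion,
                           variance=variance, car1=car1, max_outer=max_outer)
        except ConvergenceError:
            failures += 1
            continue
        est_rows.append({n: getattr(fit.params, n) for n in names})
        cover_rows.append({
            n: abs(getattr(fit.params, n) - truth[n]) <= 1.96 * fit.se[n]
            for n in names
        })
    if not est_rows:
        raise ConvergenceError(f"all {n_replicates} replicates failed to converge")
    est = pd.DataFrame(est_rows)
    cov = pd.DataFrame(cover_rows)
    out = pd.DataFrame({
        "param": list(names),
        "truth": [truth[n] for n in names],
        "mean_est": [est[n].mean() for n in names],
        "bias": [est[n].mean() - truth[n] for n in names],
        "emp_se": [est[n].std(ddof=1) if len(est) > 1 else np.nan for n in names],
        "coverage95": [cov[n].mean() for n in names],
    })
    out.attrs["n_replicates"] = n_replicates
    out.attrs["n_failed"] = failures
    return out
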