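"""Coefficient-set serialization and the packaged published sets.

A coefficient set is a flat YAML mapping: the nine profile coefficients,
the active subset, and (for mixed models) the random-effect structure and
variance components.  Two published sets for maritime pine in Asturias
(NW Spain) ship with the package:

``asturias-ols``
    Fixed-effects model fitted by ordinary least squares to the whole
    420-tree dataset.
``asturias-mm3``
    The recommended two-level mixed model with random effects on a1 and
    b3 at plot and tree level, power-of-DBH variance function, fitted by
    REML to the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .covariance import RandomSpec, TaperMixedModel, VarComp
from .exceptions import ConfigurationError
from .taper import FixedParams, PARAM_NAMES

__all__ = ["CoefficientSet", "load_coefficient_set", "save_coefficient_set", "PACKAGED_SETS"]

PACKAGED_SETS = ("asturias-ols", "asturias-mm3")


@dataclass(frozen=True)
class CoefficientSet:
    """A named, serializable bundle of coefficients (+ optional random structure)."""

    params: FixedParams
    label: str = ""
    sigma2: float | None = None
    spec: RandomSpec | None = None
    varcomp: VarComp | None = None

    def mixed_model(self) -> TaperMixedModel:
        if self.spec is None or self.varcomp is None:
            raise ConfigurationError(
                f"coefficient set '{self.label}' carries no random-effect structure"
            )
        return TaperMixedModel(self.params, self.spec, self.varcomp)


def _from_mapping(doc: dict, label: str) -> CoefficientSet:
    try:
        pvals = {k: float(v) for k, v in doc["params"].items()}
    except KeyError as e:
        raise ConfigurationError(f"coefficient file missing section {e}") from e
    unknown = set(pvals) - set(PARAM_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown coefficient name(s): {sorted(unknown)}")
    active = tuple(doc.get("active", [n for n in PARAM_NAMES if n in pvals]))
    params = FixedParams(**pvals, active=active)
    spec = varcomp = None
    sigma2 = doc.get("sigma2")
    if "random" in doc:
        r = doc["random"]
        spec = RandomSpec(tuple(r["expanded"]))
        varcomp = VarComp(
            sigma2=float(r["sigma2"]),
            D_p=np.asarray(r["D_p"], float),
            D_t=np.asarray(r["D_t"], float),
            delta=float(r.get("delta", 0.0)),
            phi=None if r.get("phi") is None else float(r["phi"]),
        )
        sigma2 = varcomp.sigma2
    return CoefficientSet(
        params=params,
        label=doc.get("label", label),
        sigma2=None if sigma2 is None else float(sigma2),
        spec=spec,
        varcomp=varcomp,
    )


def load_coefficient_set(name_or_path: str | Path) -> CoefficientSet:
    """Load a coefficient set by packaged name or filesystem path."""
    name = str(name_or_path)
    if name in PACKAGED_SETS:
        text = resources.files("tapermix").joinpath(f"coeffs/{name}.yaml").read_text()
        return _from_mapping(yaml.safe_load(text), label=name)
    path = Path(name_or_path)
    if not path.exists():
        raise ConfigurationError(
            f"'{name}' is neither a packaged set {PACKAGED_SETS} nor an existing file"
        )
    return _from_mapping(yaml.safe_load(path.read_text()), label=path.stem)


def save_coefficient_set(cs: CoefficientSet, path: str | Path) -> None:
    """Write a coefficient set as flat YAML (round-trips with the loader)."""
    doc: dict = {
        "label": cs.label,
        "params": {n: float(getattr(cs.params, n)) for n in cs.params.active},
        "active": list(cs.params.active),
    }
    if cs.varcomp is not None and cs.spec is not None:
        vc = cs.varcomp
        doc["random"] = {
            "expanded": list(cs.spec.expanded),
            "D_p": vc.D_p.tolist(),
            "D_t": vc.D_t.tolist(),
            "sigma2": float(vc.sigma2),
            "delta": float(vc.delta),
            "phi": None if vc.phi is None else float(vc.phi),
        }
    elif cs.sigma2 is not None:
        doc["sigma2"] = float(cs.sigma2)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
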