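"""Hierarchical stem-taper measurements: containers, delimited-text I/O,
observed volumes and the fitting/evaluation split.

Units are fixed throughout the package: heights in metres, diameters in
centimetres, volumes in cubic metres.  Unit conversion happens only inside
volume routines (a diameter ``d_i`` cm corresponds to a radius
``d_i / 200`` m).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "SectionObs",
    "TreeRecord",
    "TaperDataset",
    "DEFAULT_DIALECT",
    "read_taper_csv",
    "write_taper_csv",
    "observed_stem_volume",
    "split_by_plot",
]

#: Logical field -> default column name in delimited files.
DEFAULT_DIALECT: Mapping[str, str] = {
    "plot": "plot",
    "tree": "tree",
    "d": "dbh",
    "h": "htot",
    "h_i": "hsec",
    "d_i": "dsec",
}


@dataclass(frozen=True)
class SectionObs:
    """One crosscut section: height above ground (m) and over-bark diameter (cm)."""

    h_i: float
    d_i: float

    def __post_init__(self):
        if not (self.h_i >= 0.0):
            raise ValidationError(f"section height must be >= 0, got {self.h_i}")
        if not (self.d_i >= 0.0):
            raise ValidationError(f"section diameter must be >= 0, got {self.d_i}")


@dataclass(frozen=True)
class TreeRecord:
    """A felled tree: identifiers, DBH ``d`` (cm), total height ``h`` (m),
    optional stump height, and its ordered stem sections."""

    plot_id: str
    tree_id: str
    d: float
    h: float
    sections: tuple[SectionObs, ...]
    h_st: float | None = None

    def __post_init__(self):
        if not self.d > 0:
            raise ValidationError(f"tree {self.key}: DBH must be > 0, got {self.d}")
        if not self.h > 1.3:
            raise ValidationError(
                f"tree {self.key}: total height must exceed breast height "
                f"(1.3 m), got {self.h}"
            )
        if len(self.sections) < 1:
            raise ValidationError(f"tree {self.key}: needs at least one section")
        secs = tuple(sorted(self.sections, key=lambda s: s.h_i))
        hs = [s.h_i for s in secs]
        if len(set(hs)) != len(hs):
            raise ValidationError(f"tree {self.key}: duplicate section heights {hs}")
        if hs[-1] > self.h:
            raise ValidationError(
                f"tree {self.key}: section height {hs[-1]} exceeds total height {self.h}"
            )
        object.__setattr__(self, "sections", secs)

    @property
    def key(self) -> tuple[str, str]:
        return (self.plot_id, self.tree_id)

    @property
    def section_heights(self) -> np.ndarray:
        return np.array([s.h_i for s in self.sections])

    @property
    def section_diameters(self) -> np.ndarray:
        return np.array([s.d_i for s in self.sections])

    def with_sections(self, sections: Sequence[SectionObs]) -> "TreeRecord":
        return replace(self, sections=tuple(sections))


@dataclass(frozen=True)
class TaperDataset:
    """A plot -> tree -> section hierarchy of taper measurements."""

    trees: tuple[TreeRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "trees", tuple(self.trees))
        keys = [t.key for t in self.trees]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValidationError(f"duplicate (plot, tree) identifiers: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[TreeRecord]:
        return iter(self.trees)

    @property
    def plot_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.trees:
            seen.setdefault(t.plot_id, None)
        return tuple(seen)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_sections(self) -> int:
        return sum(len(t.sections) for t in self.trees)

    def plots(self) -> dict[str, tuple[TreeRecord, ...]]:
        out: dict[str, list[TreeRecord]] = {}
        for t in self.trees:
            out.setdefault(t.plot_id, []).append(t)
        return {k: tuple(v) for k, v in out.items()}

    def subset_plots(self, plot_ids: Sequence[str], provenance: str = "") -> "TaperDataset":
        wanted = set(plot_ids)
        return TaperDataset(
            tuple(t for t in self.trees if t.plot_id in wanted),
            provenance or self.provenance,
        )

    def to_frame(self, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
        dia = dict(DEFAULT_DIALECT, **(dialect or {}))
        rows = [
            {
                dia["plot"]: t.plot_id,
                dia["tree"]: t.tree_id,
                dia["d"]: t.d,
                dia["h"]: t.h,
                dia["h_i"]: s.h_i,
                dia["d_i"]: s.d_i,
            }
            for t in self.trees
            for s in t.sections
        ]
        return pd.DataFrame(rows)


def _separator(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_taper_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> TaperDataset:
    """Read a delimited section-level file into a :class:`TaperDataset`.

    Each row is one stem section; tree-level fields (DBH, total height)
    are repeated on every row of a tree.  ``dialect`` maps the logical
    names ``plot, tree, d, h, h_i, d_i`` to the file's column names
    (defaults: ``plot, tree, dbh, htot, hsec, dsec``).  Sections are
    grouped by (plot, tree) and sorted by height; rows violating the
    structural invariants raise :class:`ValidationError` naming the row.
    """
    path = Path(path)
    dia = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=_separator(path))
    missing = [dia[k] for k in ("plot", "tree", "d", "h", "h_i", "d_i") if dia[k] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing required column(s) {missing}; "
            f"present: {list(df.columns)}"
        )
    numeric = {}
    for k in ("d", "h", "h_i", "d_i"):
        col = pd.to_numeric(df[dia[k]], errors="coerce")
        bad = df.index[col.isna() & df[dia[k]].notna()] + 2  # header + 1-based
        if len(bad):
            raise ValidationError(
                f"{path.name}: non-numeric value in column '{dia[k]}' at file "
                f"row(s) {list(bad[:10])}"
            )
        if col.isna().any():
            rows = list(df.index[col.isna()][:10] + 2)
            raise ValidationError(f"{path.name}: missing value in '{dia[k]}' at row(s) {rows}")
        numeric[k] = col.to_numpy(float)

    over = numeric["h_i"] > numeric["h"]
    if over.any():
        rows = list(df.index[over][:10] + 2)
        raise ValidationError(
            f"{path.name}: section height exceeds total tree height at row(s) {rows}"
        )

    trees: list[TreeRecord] = []
    group_cols = [df[dia["plot"]].astype(str), df[dia["tree"]].astype(str)]
    work = pd.DataFrame(
        {
            "plot": group_cols[0],
            "tree": group_cols[1],
            "d": numeric["d"],
            "h": numeric["h"],
            "h_i": numeric["h_i"],
            "d_i": numeric["d_i"],
            "row": df.index + 2,
        }
    )
    for (plot, tree), grp in work.groupby(["plot", "tree"], sort=True):
        if grp["h_i"].duplicated().any():
            rows = list(grp.loc[grp["h_i"].duplicated(), "row"][:10])
            raise ValidationError(
                f"{path.name}: duplicate section height for tree ({plot}, {tree}) "
                f"at row(s) {rows}"
            )
        d_vals, h_vals = grp["d"].unique(), grp["h"].unique()
        if len(d_vals) > 1 or len(h_vals) > 1:
            raise ValidationError(
                f"{path.name}: inconsistent DBH/height within tree ({plot}, {tree})"
            )
        secs = tuple(
            SectionObs(h_i=r.h_i, d_i=r.d_i)
            for r in grp.sort_values("h_i").itertuples()
        )
        trees.append(
            TreeRecord(plot_id=plot, tree_id=tree, d=float(d_vals[0]), h=float(h_vals[0]), sections=secs)
        )
    return TaperDataset(tuple(trees), provenance if provenance is not None else path.name)


def write_taper_csv(
    data: TaperDataset, path: str | Path, dialect: Mapping[str, str] | None = None
) -> None:
    """Write a dataset in the section-per-row delimited layout (full precision)."""
    path = Path(path)
    df = data.to_frame(dialect)
    df.to_csv(path, sep=_separator(path), index=False, float_format="%.17g")


def observed_stem_volume(tree: TreeRecord) -> float:
    """Observed over-bark stem volume (m^3) from the measured sections.

    Consecutive sections form conical frustums; the top piece, from the
    last section to the tip, is a cone.  Radii in metres are ``d_i / 200``.
    """
    if len(tree.sections) < 2:
        raise ValidationError(
            f"tree {tree.key}: need at least 2 sections to compute an observed volume"
        )
    h = tree.section_heights
    r = tree.section_diameters / 200.0
    L = np.diff(h)
    frustums = (np.pi * L / 3.0) * (r[:-1] ** 2 + r[:-1] * r[1:] + r[1:] ** 2)
    cone = (np.pi * (tree.h - h[-1]) / 3.0) * r[-1] ** 2
    return float(frustums.sum() + cone)


def split_by_plot(
    data: TaperDataset, fit_fraction: float, seed: int
) -> tuple[TaperDataset, TaperDataset]:
    """Randomly split whole plots into a fitting and an evaluation dataset.

    The fitting side receives ``round(fit_fraction * n_plots)`` plots; trees
    of one plot are never separated.  Reproducible for a fixed seed.
    """
    if not 0.0 < fit_fraction < 1.0:
        raise ValueError(f"fit_fraction must lie in (0, 1), got {fit_fraction}")
    plot_ids = list(data.plot_ids)
    if len(plot_ids) < 2:
        raise ValidationError("need at least 2 plots to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plot_ids))
    n_fit = int(round(fit_fraction * len(plot_ids)))
    n_fit = min(max(n_fit, 1), len(plot_ids) - 1)
    fit_ids = {plot_ids[i] for i in order[:n_fit]}
    fit = data.subset_plots([p for p in plot_ids if p in fit_ids], provenance=f"{data.provenance}[fit]")
    ev = data.subset_plots([p for p in plot_ids if p not in fit_ids], provenance=f"{data.provenance}[eval]")
    return fit, ev
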