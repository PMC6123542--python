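"""Metabolite quantification from binned spectra, and STOCSY.

An assignment table maps named metabolites to chemical-shift windows; a
metabolite's relative abundance is the weighted sum of the integrals of
all bins whose midpoint falls inside one of its windows.  STOCSY
(statistical total correlation spectroscopy) correlates one driver
feature against every feature across samples; resonances of the same
molecule share a concentration driver and therefore correlate strongly,
which supports peak assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinTable
from .spectra import SpectraSet

__all__ = [
    "AssignmentTable",
    "load_default_assignments",
    "ConcentrationTable",
    "integrate_metabolites",
    "stocsy",
]


@dataclass
class AssignmentTable:
    """Rows of (metabolite, window_lo, window_hi, weight)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"metabolite", "window_lo", "window_hi", "weight"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"assignment table missing columns {sorted(missing)}")
        t = self.table
        if (t["weight"] <= 0).any():
            raise ValueError("assignment weights must be > 0")
        if (t["window_lo"] >= t["window_hi"]).any():
            raise ValueError("assignment windows must have lo < hi")
        # windows of *different* metabolites may not overlap
        rows = t.sort_values("window_lo").reset_index(drop=True)
        for k in range(len(rows) - 1):
            a, b = rows.iloc[k], rows.iloc[k + 1]
            if a["window_hi"] > b["window_lo"] and a["metabolite"] != b["metabolite"]:
                raise ValueError(
                    f"windows of {a['metabolite']!r} and {b['metabolite']!r} overlap"
                )

    @property
    def metabolites(self) -> list[str]:
        return list(dict.fromkeys(self.table["metabolite"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssignmentTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_default_assignments(matrix_kind: str) -> AssignmentTable:
    """Packaged assignment windows for the liver / serum libraries."""
    if matrix_kind not in ("liver", "serum"):
        raise ValueError(f"unknown matrix_kind {matrix_kind!r}; use 'liver' or 'serum'")
    p = Path(str(resources.files("fibromet.data").joinpath(f"{matrix_kind}_assignments.tsv")))
    return AssignmentTable.from_tsv(p)


@dataclass
class ConcentrationTable:
    """Samples x metabolites relative abundances."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate metabolite columns")

    def group_values(self, annotations: pd.DataFrame, group: str) -> pd.DataFrame:
        ids = annotations.loc[annotations["group"] == group, "sample_id"]
        return self.values.loc[ids]


def integrate_metabolites(b: BinTable, a: AssignmentTable) -> ConcentrationTable:
    """Sum bin integrals into named-metabolite abundances.

    A bin belongs to a window when its midpoint lies in [lo, hi); windows
    matching no bin are dropped with a warning and recorded in provenance.
    """
    if not len(a.table):
        warnings.warn("empty assignment table; empty concentration table", stacklevel=2)
        empty = pd.DataFrame(index=b.values.index)
        return ConcentrationTable(empty, {"unmatched_windows": []})
    mids = b.midpoints
    out = pd.DataFrame(0.0, index=b.values.index, columns=a.metabolites)
    unmatched = []
    matched_any = {m: False for m in a.metabolites}
    for row in a.table.itertuples(index=False):
        sel = (mids >= row.window_lo) & (mids < row.window_hi)
        if not sel.any():
            unmatched.append((row.metabolite, float(row.window_lo), float(row.window_hi)))
            continue
        matched_any[row.metabolite] = True
        out[row.metabolite] += row.weight * b.values.loc[:, sel].sum(axis=1)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} assignment window(s) matched no bin: {unmatched}",
            stacklevel=2,
        )
    dropped = [m for m, ok in matched_any.items() if not ok]
    out = out.drop(columns=dropped)
    prov = {"unmatched_windows": unmatched, "dropped_metabolites": dropped, **b.provenance}
    return ConcentrationTable(out, prov)


def stocsy(data: SpectraSet | BinTable, driver: float) -> pd.DataFrame:
    """Correlation/covariance profile of one driver feature vs all features.

    ``driver`` is a ppm position: for a :class:`SpectraSet` the nearest
    axis point is used; for a :class:`BinTable` the bin whose interval
    contains it.  Returns a DataFrame ordered by ppm with columns
    ``ppm``, ``r``, ``cov``.
    """
    if isinstance(data, SpectraSet):
        X = data.intensities
        ppm = data.ppm
        idx = int(np.argmin(np.abs(ppm - driver)))
        step = np.median(np.diff(ppm))
        if abs(ppm[idx] - driver) > 2 * step:
            raise ValueError(f"driver {driver} ppm not on the retained axis")
    elif isinstance(data, BinTable):
        X = data.values.to_numpy(dtype=float)
        ppm = data.midpoints
        hits = [k for k, (lo, hi) in enumerate(data.bins) if lo <= driver < hi]
        if not hits:
            raise ValueError(f"driver {driver} ppm falls in no bin (excised region?)")
        idx = hits[0]
    else:
        raise TypeError("stocsy expects a SpectraSet or BinTable")
    if X.shape[0] < 3:
        raise ValueError("STOCSY needs >= 3 samples")
    d = X[:, idx]
    Xc = X - X.mean(axis=0)
    dc = d - d.mean()
    cov = dc @ Xc / (X.shape[0] - 1)
    sd = X.std(axis=0, ddof=1)
    dsd = d.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sd * dsd)
    r[~np.isfinite(r)] = 0.0
    out = pd.DataFrame({"ppm": ppm, "r": r, "cov": cov})
    return out.sort_values("ppm").reset_index(drop=True)
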