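"""Containers and I/O for 1D NMR spectra.

A :class:`SpectraSet` holds a cohort of 1D spectra on a shared, strictly
ascending chemical-shift (ppm) axis together with per-sample annotations
(sample id, group, matrix kind).  Spectra are exchanged as plain matrix
CSV files (first column ``ppm``, one column per sample) or as single-block
JCAMP-DX files in the common ``(X++(Y..Y))`` AFFN form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "read_spectra",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_annotations",
    "write_annotations",
    "read_jcamp",
    "write_jcamp",
    "excise_region",
]

#: relative axis-mismatch tolerated before samples are re-interpolated
AXIS_RTOL = 1e-9


@dataclass
class SpectraSet:
    """Aligned sample x spectral-point intensity matrix.

    Parameters
    ----------
    ppm:
        Strictly ascending chemical-shift axis, length ``n_points``.
    intensities:
        Array of shape ``(n_samples, n_points)``.
    annotations:
        DataFrame with columns ``sample_id``, ``group``, ``matrix_kind``;
        one row per sample, in matrix row order.
    excised:
        Record of (lo, hi) ppm intervals removed from the axis.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    annotations: pd.DataFrame
    excised: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be one-dimensional")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError(
                f"axis length {self.ppm.size} != matrix column count "
                f"{self.intensities.shape[1]}"
            )
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain missing/non-finite values")
        ann = self.annotations
        if len(ann) != self.intensities.shape[0]:
            raise ValueError("annotation row count != sample count")
        for col in ("sample_id", "group", "matrix_kind"):
            if col not in ann.columns:
                raise ValueError(f"annotations missing column {col!r}")
        if ann["sample_id"].duplicated().any():
            dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.annotations["sample_id"].astype(str).tolist()

    def groups(self) -> pd.Series:
        return self.annotations.set_index("sample_id")["group"]

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.ppm.copy(),
            self.intensities.copy(),
            self.annotations.copy(),
            list(self.excised),
        )


# ---------------------------------------------------------------------------
# matrix CSV + annotations TSV

def write_matrix_csv(s: SpectraSet, path: str | Path) -> None:
    """Write spectra as CSV: first column ``ppm``, one column per sample."""
    df = pd.DataFrame(s.intensities.T, columns=s.sample_ids)
    df.insert(0, "ppm", s.ppm)
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))  # lossless round trip


def write_annotations(s: SpectraSet, path: str | Path) -> None:
    s.annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group", "matrix_kind"} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns {sorted(missing)}")
    return ann


def read_matrix_csv(path: str | Path, annotations: pd.DataFrame | str | Path | None = None) -> SpectraSet:
    """Read a spectra matrix CSV (first column ppm, one column per sample)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "ppm":
        raise ValueError(f"{path}: first column must be 'ppm', got {df.columns[0]!r}")
    ppm = df["ppm"].to_numpy(dtype=float)
    inten = df.drop(columns="ppm").to_numpy(dtype=float).T
    ids = [str(c) for c in df.columns[1:]]
    if ppm[0] > ppm[-1]:  # stored descending: reverse, keeping pairing
        ppm = ppm[::-1]
        inten = inten[:, ::-1]
    if annotations is None:
        ann = pd.DataFrame(
            {"sample_id": ids, "group": "unknown", "matrix_kind": "unknown"}
        )
    else:
        ann = annotations if isinstance(annotations, pd.DataFrame) else read_annotations(annotations)
        ann = ann.set_index("sample_id").loc[ids].reset_index()
    return SpectraSet(ppm, inten, ann)


# ---------------------------------------------------------------------------
# minimal JCAMP-DX (single spectrum per file, (X++(Y..Y)) AFFN)

def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a single-block JCAMP-DX file with ``##XYDATA=(X++(Y..Y))`` AFFN data.

    Returns ``(x, y, header)`` with x ascending.
    """
    header: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                    continue
                header[key] = value
                continue
            if in_data:
                parts = line.replace(",", " ").split()
                vals = [float(p) for p in parts]
                if len(vals) < 2:
                    raise ValueError(f"{path}: malformed XYDATA line {line!r}")
                x0 = vals[0]
                yrow = vals[1:]
                xfactor = float(header.get("XFACTOR", 1.0))
                yfactor = float(header.get("YFACTOR", 1.0))
                npts = int(float(header.get("NPOINTS", 0)))
                first = float(header.get("FIRSTX", x0 * xfactor))
                last = float(header.get("LASTX", first))
                if npts > 1:
                    dx = (last - first) / (npts - 1)
                else:
                    dx = 0.0
                start = x0 * xfactor
                for j, yv in enumerate(yrow):
                    xs.append(start + j * dx)
                    ys.append(yv * yfactor)
    if not xs:
        raise ValueError(f"{path}: no XYDATA block found")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return x, y, header


def write_jcamp(path: str | Path, x: np.ndarray, y: np.ndarray, title: str = "spectrum") -> None:
    """Write one spectrum as JCAMP-DX ``(X++(Y..Y))`` AFFN with a uniform axis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    dx = np.diff(x)
    if x.size > 1 and not np.allclose(dx, dx[0], rtol=1e-6, atol=1e-12):
        raise ValueError("JCAMP-DX writer requires a uniform axis")
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={float(x[0])!r}",
        f"##LASTX={float(x[-1])!r}",
        f"##NPOINTS={x.size}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, x.size, per_line):
        chunk = y[i : i + per_line]
        lines.append(" ".join([repr(float(x[i]))] + [repr(float(v)) for v in chunk]))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# multi-file reader

def read_spectra(
    paths: Sequence[str | Path] | str | Path,
    format: str = "matrix-csv",
    annotations: pd.DataFrame | str | Path | None = None,
) -> SpectraSet:
    """Read spectra into a :class:`SpectraSet`.

    ``matrix-csv`` expects a single CSV with all samples; ``jcamp-dx``
    expects one file per sample (sample id = file stem).  JCAMP samples on
    differing grids are linearly interpolated onto the first file's axis.
    """
    if format == "matrix-csv":
        if isinstance(paths, (list, tuple)):
            if len(paths) != 1:
                raise ValueError("matrix-csv format expects a single file")
            paths = paths[0]
        return read_matrix_csv(paths, annotations)
    if format == "jcamp-dx":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        axis = None
        rows = []
        ids = []
        for p in paths:
            x, y, _ = read_jcamp(p)
            if axis is None:
                axis = x
            elif x.shape != axis.shape or not np.allclose(x, axis, rtol=AXIS_RTOL, atol=0):
                if x[0] > axis[-1] or x[-1] < axis[0]:
                    raise ValueError(f"{p}: axis does not overlap the reference axis")
                y = np.interp(axis, x, y)
            rows.append(y)
            ids.append(Path(p).stem)
        if annotations is None:
            ann = pd.DataFrame({"sample_id": ids, "group": "unknown", "matrix_kind": "unknown"})
        else:
            ann = annotations if isinstance(annotations, pd.DataFrame) else read_annotations(annotations)
            ann = ann.set_index("sample_id").loc[ids].reset_index()
        return SpectraSet(np.asarray(axis), np.vstack(rows), ann)
    raise ValueError(f"unknown format {format!r}; use 'matrix-csv' or 'jcamp-dx'")


# ---------------------------------------------------------------------------
# water excision

def excise_region(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Remove all axis points with ``lo <= ppm <= hi`` (closed interval).

    Returns a new :class:`SpectraSet`; the removed interval is appended to
    ``excised`` provenance.  An interval containing no axis points is a
    no-op with a warning.
    """
    if not lo < hi:
        raise ValueError(f"excision requires lo < hi, got ({lo}, {hi})")
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not mask.any():
        warnings.warn(
            f"excision interval ({lo}, {hi}) contains no axis points; no-op",
            stacklevel=2,
        )
        return s.copy()
    keep = ~mask
    out = SpectraSet(
        s.ppm[keep], s.intensities[:, keep], s.annotations.copy(), list(s.excised)
    )
    if (lo, hi) not in out.excised:
        out.excised.append((lo, hi))
    return out


def axis_segments(ppm: np.ndarray, gap_factor: float = 3.0) -> list[tuple[int, int]]:
    """Split an axis into contiguous segments at gaps (e.g. excised regions).

    Returns half-open index ranges ``[i, j)``.  A gap is a step larger than
    ``gap_factor`` times the median step.
    """
    if ppm.size == 0:
        return []
    steps = np.diff(ppm)
    if steps.size == 0:
        return [(0, 1)]
    med = np.median(steps)
    breaks = np.nonzero(steps > gap_factor * med)[0]
    bounds = [0] + [int(b) + 1 for b in breaks] + [ppm.size]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
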