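"""Synthetic 1D CPMG-style NMR cohorts with known ground truth.

The generator emulates 500 MHz 1H spectra of liver extracts and serum from
a rodent liver-fibrosis study design: several dose groups, ~15 animals per
group, per-metabolite group effects expressed as log2 fold changes against
a reference (control) group.  Each metabolite is a set of Lorentzian
singlets; a sample's spectrum is

    dilution * sum_m conc[m] * sum_peaks h * L(ppm - c - jitter_m; hw)
    + baseline drift + white noise

with per-sample log-normal concentrations, a per-sample dilution factor
(exercising probabilistic quotient normalization downstream), a low-order
polynomial baseline and coherent per-metabolite chemical-shift jitter.
Concentrations, dilutions and the design are returned as ground truth so
recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SpectraSet, read_annotations, read_matrix_csv, write_annotations, write_matrix_csv

__all__ = [
    "MetaboliteLibrary",
    "CohortDesign",
    "GroundTruth",
    "load_default_library",
    "load_default_effects",
    "design_from_effects",
    "simulate_cohort",
    "default_axis",
    "write_fixture",
    "read_fixture",
]

AXIS_LO, AXIS_HI = -5.0, 15.0  # acquisition window emulated


@dataclass
class MetaboliteLibrary:
    """Per-metabolite Lorentzian peak lists.

    ``peaks`` maps metabolite name -> list of
    ``(center_ppm, relative_height, halfwidth_ppm)`` tuples.
    """

    peaks: dict[str, list[tuple[float, float, float]]]
    matrix_kind: str = "custom"

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("library is empty")
        for name, plist in self.peaks.items():
            if not plist:
                raise ValueError(f"metabolite {name!r} has no peaks")
            heights = [h for _, h, _ in plist]
            if any(h < 0 for h in heights) or sum(heights) <= 0:
                raise ValueError(f"metabolite {name!r}: relative heights must be >=0 and sum > 0")
            for c, _, hw in plist:
                if hw <= 0:
                    raise ValueError(f"metabolite {name!r}: halfwidth must be > 0")
                if not AXIS_LO <= c <= AXIS_HI:
                    raise ValueError(
                        f"metabolite {name!r}: peak at {c} ppm outside {AXIS_LO}..{AXIS_HI}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class CohortDesign:
    """Cohort layout and generative parameters.

    ``effects[(group, metabolite)]`` is the designed log2 fold change of
    that group's mean concentration against the reference group (the first
    group listed); entries for the reference group must be 0 (or absent).
    """

    groups: list[tuple[str, int]]
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_concentration: dict[str, float] = field(default_factory=dict)
    dilution_range: tuple[float, float] = (0.5, 2.0)
    sigma_log2: float = 0.3
    noise_sd: float = 0.005
    baseline_amplitude: float = 0.005
    shift_jitter_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for g, n in self.groups:
            if n < 2:
                raise ValueError(f"group {g!r}: n_samples must be >= 2")
        lo, hi = self.dilution_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid dilution_range {self.dilution_range}")
        ref = labels[0]
        for (g, m), e in self.effects.items():
            if g == ref and e != 0:
                raise ValueError(f"reference group {ref!r} must have all effects = 0")
            if g not in labels:
                raise ValueError(f"effect refers to unknown group {g!r}")
        if self.noise_sd < 0 or self.shift_jitter_sd < 0 or self.sigma_log2 < 0:
            raise ValueError("noise_sd, shift_jitter_sd and sigma_log2 must be >= 0")

    @property
    def reference_group(self) -> str:
        return self.groups[0][0]


@dataclass
class GroundTruth:
    """Generated per-sample truth: concentrations, dilutions, design echo."""

    concentrations: pd.DataFrame  # samples x metabolites
    dilution: pd.Series  # per sample
    design: CohortDesign

    def mean_log2_ratio(self, group: str, metabolite: str, reference: str | None = None) -> float:
        """Realized log2 ratio of group-mean concentrations vs the reference."""
        ref = reference or self.design.reference_group
        ann = self.concentrations.index.to_series().str.rsplit("-", n=1).str[0]
        a = self.concentrations.loc[ann == group, metabolite].mean()
        b = self.concentrations.loc[ann == ref, metabolite].mean()
        return float(np.log2(a / b))


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str) -> Path:
    return Path(str(resources.files("fibromet.data").joinpath(name)))


def load_default_library(matrix_kind: str) -> MetaboliteLibrary:
    """Load the packaged liver (39 metabolites) or serum (28) peak library."""
    if matrix_kind not in ("liver", "serum"):
        raise ValueError(f"unknown matrix_kind {matrix_kind!r}; use 'liver' or 'serum'")
    df = pd.read_csv(_data_path(f"{matrix_kind}_library.tsv"), sep="\t")
    peaks: dict[str, list[tuple[float, float, float]]] = {}
    for row in df.itertuples(index=False):
        peaks.setdefault(row.metabolite, []).append(
            (float(row.center_ppm), float(row.rel_height), float(row.halfwidth_ppm))
        )
    return MetaboliteLibrary(peaks, matrix_kind=matrix_kind)


def load_default_effects(matrix_kind: str) -> pd.DataFrame:
    """Packaged per-metabolite log2 fold-change table (one column per contrast)."""
    if matrix_kind not in ("liver", "serum"):
        raise ValueError(f"unknown matrix_kind {matrix_kind!r}; use 'liver' or 'serum'")
    return pd.read_csv(_data_path(f"{matrix_kind}_effects.tsv"), sep="\t").set_index("metabolite")


def design_from_effects(
    effects: pd.DataFrame,
    groups: Sequence[tuple[str, int]] = (("control", 15), ("model", 15)),
    **kwargs,
) -> CohortDesign:
    """Build a :class:`CohortDesign` from a packaged effects table.

    The table's contrast columns are ``model_vs_control`` and
    ``<dose>_vs_model``; group effects against the control reference are
    composed accordingly (e.g. low = model_vs_control + low_vs_model).
    Groups named outside {control, model, low, medium, high} get zero effect.
    """
    labels = [g for g, _ in groups]
    if labels[0] != "control":
        raise ValueError("reference (first) group must be 'control'")
    eff: dict[tuple[str, str], float] = {}
    for m, row in effects.iterrows():
        mvc = float(row.get("model_vs_control", 0.0))
        for g in labels[1:]:
            if g == "model":
                eff[(g, m)] = mvc
            elif f"{g}_vs_model" in effects.columns:
                eff[(g, m)] = mvc + float(row[f"{g}_vs_model"])
            else:
                eff[(g, m)] = 0.0
    return CohortDesign(groups=list(groups), effects=eff, **kwargs)


def default_axis(n_points: int = 2048, lo: float = 0.0, hi: float = 10.0) -> np.ndarray:
    """Default simulation axis: 2048 points over 0..10 ppm (fast, covers the
    packaged libraries); the full acquisition window -5..15 ppm at 64 K is
    supported by passing other bounds/sizes."""
    return np.linspace(lo, hi, n_points)


# ---------------------------------------------------------------------------
# forward model

def _lorentzian(ppm: np.ndarray, center: float, height: float, hw: float) -> np.ndarray:
    # height-parameterized absorption Lorentzian; area = height * hw * pi
    return height * hw**2 / ((ppm - center) ** 2 + hw**2)


def simulate_cohort(
    library: MetaboliteLibrary,
    design: CohortDesign,
    axis: np.ndarray | None = None,
) -> tuple[SpectraSet, GroundTruth]:
    """Draw a cohort of spectra plus ground truth from the forward model.

    A fixed ``design.seed`` gives bit-identical output.
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be strictly ascending, length >= 2")
    rng = np.random.default_rng(design.seed)
    names = library.names
    ref = design.reference_group

    sample_ids: list[str] = []
    group_col: list[str] = []
    conc_rows = []
    for g, n in design.groups:
        mu = np.array(
            [
                np.log2(design.baseline_concentration.get(m, 1.0))
                + design.effects.get((g, m), 0.0)
                for m in names
            ]
        )
        draws = rng.normal(loc=mu, scale=design.sigma_log2, size=(n, len(names)))
        conc_rows.append(2.0**draws)
        sample_ids.extend(f"{g}-{i+1:02d}" for i in range(n))
        group_col.extend([g] * n)
    conc = np.vstack(conc_rows)
    n_total = conc.shape[0]

    lo, hi = design.dilution_range
    dilution = rng.uniform(lo, hi, size=n_total)
    jitter = rng.normal(0.0, design.shift_jitter_sd, size=(n_total, len(names)))

    inten = np.zeros((n_total, axis.size))
    for j, m in enumerate(names):
        for c, h, hw in library.peaks[m]:
            centers = c + jitter[:, j]  # coherent shift of all of m's peaks
            inten += (
                conc[:, j, None]
                * h
                * hw**2
                / ((axis[None, :] - centers[:, None]) ** 2 + hw**2)
            )
    inten *= dilution[:, None]

    if design.baseline_amplitude > 0:
        # low-order polynomial drift, small random coefficients per sample
        u = (axis - axis[0]) / (axis[-1] - axis[0]) * 2 - 1
        coefs = rng.normal(0.0, design.baseline_amplitude, size=(n_total, 3))
        drift = (
            coefs[:, [0]]
            + coefs[:, [1]] * u[None, :]
            + coefs[:, [2]] * (u[None, :] ** 2)
        )
        inten += drift
    if design.noise_sd > 0:
        inten += rng.normal(0.0, design.noise_sd, size=inten.shape)

    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group_col,
            "matrix_kind": library.matrix_kind,
        }
    )
    spectra = SpectraSet(axis, inten, ann)
    truth = GroundTruth(
        concentrations=pd.DataFrame(conc, index=sample_ids, columns=names),
        dilution=pd.Series(dilution, index=sample_ids, name="dilution"),
        design=design,
    )
    return spectra, truth


# ---------------------------------------------------------------------------
# fixtures on disk

def write_fixture(spectra: SpectraSet, truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write spectra (CSV), annotations (TSV) and truth tables (TSV).

    Round-trips losslessly through :func:`read_fixture` /
    :func:`fibromet.spectra.read_matrix_csv`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {
        "spectra": d / "spectra.csv",
        "annotations": d / "annotations.tsv",
        "concentrations": d / "truth_concentrations.tsv",
        "dilution": d / "truth_dilution.tsv",
    }
    write_matrix_csv(spectra, files["spectra"])
    write_annotations(spectra, files["annotations"])
    truth.concentrations.rename_axis("sample_id").to_csv(
        files["concentrations"], sep="\t", float_format=lambda v: repr(float(v))
    )
    truth.dilution.rename_axis("sample_id").to_frame().to_csv(
        files["dilution"], sep="\t", float_format=lambda v: repr(float(v))
    )
    return files


def read_fixture(directory: str | Path) -> tuple[SpectraSet, pd.DataFrame, pd.Series]:
    """Read back a fixture directory: (spectra, concentrations, dilution)."""
    d = Path(directory)
    ann = read_annotations(d / "annotations.tsv")
    spectra = read_matrix_csv(d / "spectra.csv", ann)
    conc = pd.read_csv(
        d / "truth_concentrations.tsv", sep="\t", index_col="sample_id",
        float_precision="round_trip",
    )
    dil = pd.read_csv(
        d / "truth_dilution.tsv", sep="\t", index_col="sample_id",
        float_precision="round_trip",
    )["dilution"]
    return spectra, conc, dil
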