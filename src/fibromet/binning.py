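"""Adaptive spectral binning (bucketing).

Bin boundaries are placed at local minima of the cohort-mean spectrum:
starting from each contiguous axis segment (segments are delimited by
excised regions), a bin wider than ``min_width`` is split at its deepest
interior local minimum whenever that minimum is prominent — its depth
below the smaller flanking maximum exceeds ``min_prominence`` times that
maximum — and bins still wider than ``max_width`` are force-split into
equal parts.  A noise floor (estimated from the median absolute first
difference of the mean spectrum) suppresses prominence splits in
signal-free regions, so quiet stretches yield a few wide bins rather than
hundreds of noise slivers; this keeps the downstream PQN median quotient
anchored on signal-carrying features.

Bin values are per-sample trapezoidal integrals.  Adjacent bins share
their boundary point, so the bin integrals of a segment sum exactly to
the segment's total trapezoidal integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraSet, axis_segments

__all__ = ["BinTable", "adaptive_bin"]


@dataclass
class BinTable:
    """Ordered ppm intervals and per-sample integrals.

    ``bins`` is a list of half-open intervals ``[lo, hi)``;  ``values`` is a
    samples x bins DataFrame (rows indexed by sample id).
    """

    bins: list[tuple[float, float]]
    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bins) != self.values.shape[1]:
            raise ValueError("bin count != value column count")
        for (lo, hi), (lo2, _) in zip(self.bins, self.bins[1:]):
            if hi > lo2 + 1e-12:
                raise ValueError("bins overlap or are unsorted")

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.bins])

    @property
    def widths(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.bins])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: bin_lo, bin_hi, one column per sample."""
        df = pd.DataFrame(
            {
                "bin_lo": [lo for lo, _ in self.bins],
                "bin_hi": [hi for _, hi in self.bins],
            }
        )
        vals = self.values.T.reset_index(drop=True)
        vals.columns = self.values.index
        return pd.concat([df, vals], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "BinTable":
        bins = list(zip(df["bin_lo"].astype(float), df["bin_hi"].astype(float)))
        values = df.drop(columns=["bin_lo", "bin_hi"]).T
        values.index.name = "sample_id"
        return cls(bins, values, provenance or {})


def _local_minima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau interior local minima of y."""
    if y.size < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, y.size - 1)
    is_min = (y[interior] <= y[interior - 1]) & (y[interior] <= y[interior + 1]) & (
        (y[interior] < y[interior - 1]) | (y[interior] < y[interior + 1])
    )
    return interior[is_min]


def _split_recursive(
    ppm: np.ndarray,
    mean: np.ndarray,
    i: int,
    j: int,
    min_width: float,
    max_width: float,
    min_prominence: float,
    noise_floor: float,
    out: list[tuple[int, int]],
) -> None:
    """Recursively split index range [i, j] (inclusive endpoints)."""
    width = ppm[j] - ppm[i]
    seg = mean[i : j + 1]
    if width > min_width and seg.size >= 3:
        minima = _local_minima(seg)
        best_k, best_depth = -1, 0.0
        for k in minima:
            left_max = seg[: k + 1].max()
            right_max = seg[k:].max()
            flank = min(left_max, right_max)
            depth = flank - seg[k]
            if flank > noise_floor and depth > min_prominence * flank and depth > best_depth:
                best_depth, best_k = depth, int(k)
        if best_k > 0:
            _split_recursive(ppm, mean, i, i + best_k, min_width, max_width,
                             min_prominence, noise_floor, out)
            _split_recursive(ppm, mean, i + best_k, j, min_width, max_width,
                             min_prominence, noise_floor, out)
            return
    if width > max_width:
        n_parts = int(np.ceil(width / max_width))
        # equal-width force splits at the nearest grid points
        edges = [i]
        for p in range(1, n_parts):
            target = ppm[i] + width * p / n_parts
            k = i + int(np.searchsorted(ppm[i : j + 1], target))
            if k <= edges[-1]:
                k = edges[-1] + 1
            if k >= j:
                break
            edges.append(k)
        edges.append(j)
        for a, b in zip(edges, edges[1:]):
            out.append((a, b))
        return
    out.append((i, j))


def adaptive_bin(
    s: SpectraSet,
    min_width: float = 0.01,
    max_width: float = 0.12,
    min_prominence: float = 0.05,
) -> BinTable:
    """Adaptively bin a cohort and integrate each bin per sample."""
    if not min_width < max_width:
        raise ValueError("min_width must be < max_width")
    if s.ppm.size == 0 or s.n_samples == 0:
        raise ValueError("empty spectra")
    mean = s.intensities.mean(axis=0)
    segments = axis_segments(s.ppm)

    if np.allclose(mean, 0.0):
        # degenerate all-zero input: one bin per retained segment
        ranges = [(i, j - 1) for i, j in segments if j - i >= 2]
    else:
        diffs = np.abs(np.diff(mean))
        noise_floor = 5.0 * float(np.median(diffs)) if diffs.size else 0.0
        ranges = []
        for i, j in segments:
            if j - i < 2:
                continue
            _split_recursive(
                s.ppm, mean, i, j - 1, min_width, max_width, min_prominence,
                noise_floor, ranges,
            )
        ranges.sort()

    bins = [(float(s.ppm[a]), float(s.ppm[b])) for a, b in ranges]
    vals = np.empty((s.n_samples, len(ranges)))
    for col, (a, b) in enumerate(ranges):
        vals[:, col] = np.trapezoid(s.intensities[:, a : b + 1], s.ppm[a : b + 1], axis=1)
    values = pd.DataFrame(vals, index=s.sample_ids, columns=range(len(bins)))
    values.index.name = "sample_id"
    prov = {
        "min_width": min_width,
        "max_width": max_width,
        "min_prominence": min_prominence,
        "excised": list(s.excised),
    }
    return BinTable(bins, values, prov)
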