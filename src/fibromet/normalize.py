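"""Dilution correction and scaling for binned NMR features.

:class:`PQNNormalizer` implements probabilistic quotient normalization:
each sample is divided by the median of its feature-wise quotients against
a reference spectrum (the median spectrum of all samples, or of a chosen
control group).  :class:`ParetoScaler` mean-centers each feature and
divides by the square root of its standard deviation (n-1 denominator).
Both are scikit-learn transformers so they compose with pipelines and are
re-estimated inside cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .binning import BinTable

__all__ = ["PQNNormalizer", "ParetoScaler", "FeatureMatrix", "pqn_normalize", "pareto_scale"]


@dataclass
class FeatureMatrix:
    """Samples x features matrix plus normalization/scaling provenance."""

    values: pd.DataFrame
    normalization_factors: pd.Series | None = None
    scaling: pd.DataFrame | None = None  # per-feature mean, sqrt_sd
    provenance: dict = field(default_factory=dict)


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index, X.columns
    X = np.asarray(X, dtype=float)
    return X, None, None


class PQNNormalizer(BaseEstimator, TransformerMixin):
    """Probabilistic quotient normalization.

    Parameters
    ----------
    reference:
        ``"median-all"`` (default) uses the feature-wise median over all
        fitted samples as the reference spectrum; ``"median-control"``
        uses the median over the samples of ``control_group`` (requires
        ``groups`` passed to :meth:`fit`).
    min_reference_fraction:
        Quotients are computed only on signal-carrying features: those
        whose reference value exceeds this fraction of the largest
        reference value (plus any non-positive reference, always
        excluded).  Noise-floor bins carry dilution information poorly
        and can dominate the median in sparse spectra.
    """

    def __init__(
        self,
        reference: str = "median-all",
        control_group: str | None = None,
        min_reference_fraction: float = 0.01,
    ):
        self.reference = reference
        self.control_group = control_group
        self.min_reference_fraction = min_reference_fraction

    def fit(self, X, y=None, groups=None):
        V, idx, cols = _as_array(X)
        if self.reference == "median-all":
            ref = np.median(V, axis=0)
        elif self.reference == "median-control":
            if groups is None or self.control_group is None:
                raise ValueError("median-control reference needs groups= and control_group=")
            mask = np.asarray(pd.Series(groups) == self.control_group)
            if not mask.any():
                raise ValueError(f"no samples in control group {self.control_group!r}")
            ref = np.median(V[mask], axis=0)
        else:
            raise ValueError(f"unknown reference {self.reference!r}")
        self.reference_spectrum_ = ref
        floor = self.min_reference_fraction * ref.max() if ref.max() > 0 else 0.0
        self.used_features_ = ref > max(floor, 0.0)
        if not self.used_features_.any():
            raise ValueError("reference spectrum has no strictly positive features")
        self.feature_names_ = list(cols) if cols is not None else None
        return self

    def compute_factors(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_spectrum_")
        V, idx, _ = _as_array(X)
        use = self.used_features_
        quotients = V[:, use] / self.reference_spectrum_[use]
        factors = np.median(quotients, axis=1)
        bad = ~(factors > 0)
        if bad.any():
            which = (
                [str(idx[i]) for i in np.nonzero(bad)[0]]
                if idx is not None
                else list(np.nonzero(bad)[0])
            )
            raise ValueError(f"non-positive PQN factor for sample(s): {which}")
        return factors

    def transform(self, X):
        V, idx, cols = _as_array(X)
        factors = self.compute_factors(X)
        out = V / factors[:, None]
        if idx is not None:
            return pd.DataFrame(out, index=idx, columns=cols)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


class ParetoScaler(BaseEstimator, TransformerMixin):
    """Mean-center, then divide by sqrt(standard deviation) per feature.

    Zero-variance features are centered but not divided (divisor 1) and
    recorded in ``constant_features_``.
    """

    def fit(self, X, y=None):
        V, _, cols = _as_array(X)
        if V.shape[0] < 2:
            raise ValueError("Pareto scaling needs >= 2 samples")
        self.mean_ = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1)
        self.constant_features_ = sd == 0
        divisor = np.sqrt(sd, where=~self.constant_features_, out=np.ones_like(sd))
        divisor[self.constant_features_] = 1.0
        self.divisor_ = divisor
        self.feature_names_ = list(cols) if cols is not None else None
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        V, idx, cols = _as_array(X)
        out = (V - self.mean_) / self.divisor_
        if idx is not None:
            return pd.DataFrame(out, index=idx, columns=cols)
        return out


# ---------------------------------------------------------------------------
# module-level surface over BinTable

def pqn_normalize(
    b: BinTable,
    reference: str = "median-all",
    control_group: str | None = None,
    groups=None,
) -> tuple[FeatureMatrix, pd.Series]:
    """PQN-normalize a bin table; returns (unscaled features, factors)."""
    V = b.values
    if (V.le(0).all(axis=1)).any():
        bad = V.index[V.le(0).all(axis=1)].tolist()
        raise ValueError(f"sample(s) with no positive features: {bad}")
    norm = PQNNormalizer(reference=reference, control_group=control_group)
    norm.fit(V, groups=groups)
    factors = pd.Series(norm.compute_factors(V), index=V.index, name="pqn_factor")
    values = V.div(factors, axis=0)
    fm = FeatureMatrix(
        values=values,
        normalization_factors=factors,
        provenance={"normalization": reference, **b.provenance},
    )
    return fm, factors


def pareto_scale(m: FeatureMatrix) -> FeatureMatrix:
    """Pareto-scale a feature matrix (after PQN)."""
    scaler = ParetoScaler().fit(m.values)
    values = scaler.transform(m.values)
    scaling = pd.DataFrame(
        {"mean": scaler.mean_, "sqrt_sd": scaler.divisor_, "constant": scaler.constant_features_},
        index=m.values.columns,
    )
    return FeatureMatrix(
        values=values,
        normalization_factors=m.normalization_factors,
        scaling=scaling,
        provenance={**m.provenance, "scaling": "pareto"},
    )
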