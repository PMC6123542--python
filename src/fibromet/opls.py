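"""Orthogonal projections to latent structures discriminant analysis.

Two-class OPLS-DA in the classic O-PLS form: the predictive weight is the
class-covariance direction ``w ~ X'y``; each orthogonal component is the
part of the current X-loading orthogonal to ``w``, and X is deflated by
its score/loading outer product before the final predictive component is
fitted.  By construction every orthogonal score has exactly zero sample
correlation with the encoded class vector, and deflation conserves
``||X||^2``.

Model quality is summarized by R2Y (explained class variance of the
training fit) and Q2Y (predictive ability under repeated stratified
two-fold cross-validation, Q2 = 1 - PRESS/SS0 on the encoded response);
significance of Q2Y is assessed with a label-permutation test using the
add-one p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .normalize import ParetoScaler

__all__ = [
    "OPLSDA",
    "fit_oplsda",
    "cross_validate_q2",
    "permutation_test",
    "PermutationResult",
    "scores_loadings_export",
]


def _encode(y, classes):
    y = np.asarray(y)
    enc = np.where(y == classes[0], -1.0, 1.0)
    return enc


class OPLSDA(BaseEstimator, ClassifierMixin):
    """Two-class OPLS-DA estimator.

    Parameters
    ----------
    n_orth:
        Number of orthogonal components (default 1, giving the usual 2-D
        scores plot: one predictive + one orthogonal axis).
    scale:
        ``None`` (default) assumes the input is already scaled (e.g. a
        Pareto-scaled feature matrix); ``"pareto"`` applies Pareto scaling
        inside :meth:`fit` (and to new data in :meth:`predict`), which is
        what cross-validation uses so scaling parameters are re-estimated
        per training fold.

    Fitted attributes (suffix ``_``) follow scikit-learn conventions:
    ``w_pred_`` (unit predictive weights), ``t_pred_``/``p_pred_``
    (predictive scores/loadings), ``orth_components_`` (list of
    ``(w_orth, t_orth, p_orth)``), ``r2y_``, ``loading_correlations_``,
    ``class_encoding_``.
    """

    def __init__(self, n_orth: int = 1, scale: str | None = None):
        self.n_orth = n_orth
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"OPLS-DA needs exactly two classes, got {classes.tolist()}")
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError("each class needs >= 2 samples")
        if X.shape[1] < 2:
            raise ValueError("need >= 2 features")
        if self.n_orth >= min(X.shape):
            raise ValueError(f"n_orth={self.n_orth} >= rank bound {min(X.shape)}")
        self.classes_ = classes
        self.class_encoding_ = {classes[0]: -1, classes[1]: +1}
        yenc = _encode(y, classes)
        self._y_mean = yenc.mean()
        yc = yenc - self._y_mean

        if self.scale == "pareto":
            self.scaler_ = ParetoScaler().fit(X)
            Xw = np.asarray(self.scaler_.transform(X))
        elif self.scale is None:
            self.scaler_ = None
            Xw = X.copy()
        else:
            raise ValueError(f"unknown scale {self.scale!r}")

        w = Xw.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("constant y or X orthogonal to y: zero predictive weight")
        w /= nw
        self.w_pred_ = w

        self.orth_components_ = []
        Xd = Xw
        for _ in range(self.n_orth):
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                break
            p = Xd.T @ t / tt
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:  # nothing orthogonal left
                break
            w_o /= n_o
            t_o = Xd @ w_o
            tt_o = t_o @ t_o
            if tt_o == 0:
                break
            p_o = Xd.T @ t_o / tt_o
            Xd = Xd - np.outer(t_o, p_o)
            self.orth_components_.append((w_o, t_o, p_o))

        t = Xd @ w
        tt = t @ t
        self.t_pred_ = t
        self.p_pred_ = Xd.T @ t / tt
        self.q_ = (yc @ t) / tt
        resid = yc - t * self.q_
        ss0 = yc @ yc
        self.r2y_ = float(1.0 - (resid @ resid) / ss0) if ss0 > 0 else 0.0

        # per-feature correlation with the predictive score, for loading coloring
        Xc = Xw - Xw.mean(axis=0)
        tc = t - t.mean()
        denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(tc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ tc) / denom
        r[~np.isfinite(r)] = 0.0
        self.loading_correlations_ = r
        self.n_features_in_ = X.shape[1]
        return self

    def _project(self, X):
        """Orthogonal-filter new data, return predictive scores."""
        check_is_fitted(self, "w_pred_")
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = np.asarray(self.scaler_.transform(X))
        for w_o, _, p_o in self.orth_components_:
            t_o = X @ w_o
            X = X - np.outer(t_o, p_o)
        return X @ self.w_pred_

    def decision_function(self, X):
        return self._project(X) * self.q_ + self._y_mean

    def predict(self, X):
        return np.where(self.decision_function(X) < 0, self.classes_[0], self.classes_[1])

    def transform(self, X):
        """Scores (t_pred, t_orth1, ...) for new data."""
        check_is_fitted(self, "w_pred_")
        Xw = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            Xw = np.asarray(self.scaler_.transform(Xw))
        cols = []
        for w_o, _, p_o in self.orth_components_:
            t_o = Xw @ w_o
            cols.append(t_o)
            Xw = Xw - np.outer(t_o, p_o)
        cols.insert(0, Xw @ self.w_pred_)
        return np.column_stack(cols)


def fit_oplsda(X, y, n_orth: int = 1, scale: str | None = None) -> OPLSDA:
    """Functional surface over :class:`OPLSDA`."""
    return OPLSDA(n_orth=n_orth, scale=scale).fit(X, y)


def _stratified_two_folds(y, rng):
    """Random stratified 2-fold assignment; both folds keep both classes."""
    y = np.asarray(y)
    fold = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        perm = rng.permutation(idx)
        half = idx.size // 2
        fold[perm[:half]] = 0
        fold[perm[half:]] = 1
    return fold


def cross_validate_q2(
    X,
    y,
    folds: int = 2,
    repeats: int = 20,
    n_orth: int = 1,
    scale: str | None = "pareto",
    seed: int | None = 0,
) -> float:
    """Repeated stratified two-fold cross-validated Q2 on the encoded response.

    Q2 = 1 - PRESS/SS0, pooling squared out-of-fold errors of the encoded
    (+/-1) class vector over all repeats; scaling is re-estimated inside
    each training fold.
    """
    if folds != 2:
        raise ValueError("the validation scheme is repeated two-fold (2-CV)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("cannot stratify: a class has < 2 samples")
    rng = np.random.default_rng(seed)
    yenc = _encode(y, classes)
    ss0 = float(((yenc - yenc.mean()) ** 2).sum())
    press = 0.0
    for _ in range(repeats):
        fold = _stratified_two_folds(y, rng)
        for f in (0, 1):
            train, test = fold != f, fold == f
            model = OPLSDA(n_orth=n_orth, scale=scale).fit(X[train], y[train])
            pred = model.decision_function(X[test])
            press += float(((yenc[test] - pred) ** 2).sum())
    return 1.0 - press / (repeats * ss0)


@dataclass
class PermutationResult:
    observed_q2: float
    permuted_q2: list[float]
    p_value: float


def permutation_test(
    X,
    y,
    n_perm: int = 99,
    seed: int = 0,
    repeats: int = 20,
    n_orth: int = 1,
    scale: str | None = "pareto",
) -> PermutationResult:
    """Label-permutation null for Q2Y.

    p = (1 + #{permuted Q2 >= observed}) / (1 + n_perm)  (add-one estimator,
    never exactly zero).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    obs = cross_validate_q2(
        X, y, repeats=repeats, n_orth=n_orth, scale=scale, seed=int(rng.integers(2**31))
    )
    permuted = []
    for _ in range(n_perm):
        yp = rng.permutation(y)
        while np.unique(yp).size < 2:  # pragma: no cover - permutation keeps labels
            yp = rng.permutation(y)
        permuted.append(
            cross_validate_q2(
                X, yp, repeats=repeats, n_orth=n_orth, scale=scale,
                seed=int(rng.integers(2**31)),
            )
        )
    p = (1 + sum(q >= obs for q in permuted)) / (1 + n_perm)
    return PermutationResult(observed_q2=obs, permuted_q2=permuted, p_value=float(p))


def scores_loadings_export(
    model: OPLSDA,
    sample_ids=None,
    groups=None,
    feature_names=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tables behind the scores plot and the correlation-colored loadings plot.

    The loading color value is |r| of each feature with the predictive
    score, on a blue(0)..red(1) scale.
    """
    check_is_fitted(model, "w_pred_")
    n = model.t_pred_.size
    scores = pd.DataFrame({"t_pred": model.t_pred_})
    if model.orth_components_:
        scores["t_orth1"] = model.orth_components_[0][1]
    scores.insert(0, "sample_id", sample_ids if sample_ids is not None else range(n))
    if groups is not None:
        scores["group"] = np.asarray(groups)
    loadings = pd.DataFrame(
        {
            "feature": feature_names
            if feature_names is not None
            else range(model.p_pred_.size),
            "p_pred": model.p_pred_,
            "r": model.loading_correlations_,
            "abs_r": np.abs(model.loading_correlations_),
        }
    )
    return scores, loadings
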