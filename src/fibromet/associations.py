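"""Metabolite-parameter canonical correlation and correlation networks.

:class:`RidgeCCA` links the metabolite block (X) to a clinical/element
panel (Y) by regularized canonical correlation analysis: both blocks are
standardized, covariance blocks are shrunk as ``cov + ridge*I``, and the
canonical pairs come from the SVD of the whitened cross-covariance.  The
first two canonical variates and each variable's correlation with them
feed the classic correlation-circle biplot (unit circle with guide radii
0.50/0.75/1.00).  Ridge regularization matters because the metabolite
count can approach the pooled sample count.

Correlation networks connect metabolites whose sample-wise Pearson
correlation exceeds a threshold (default |r| >= 0.6), carry fold-change
and significance as node attributes, and can be overlaid with a curated
biochemical-reaction edge list (gray "reaction" edges) for mechanistic
support.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .quantify import ConcentrationTable

__all__ = [
    "RidgeCCA",
    "canonical_regression",
    "build_network",
    "overlay_reactions",
    "load_default_reactions",
    "write_network",
]


def _standardize(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    return (V[:, keep] - mean[keep]) / sd[keep], keep


class RidgeCCA(BaseEstimator):
    """Regularized canonical correlation analysis (first two pairs).

    Fitted attributes: ``x_weights_``, ``y_weights_`` (columns = canonical
    pairs), ``x_scores_``, ``y_scores_``, ``canonical_correlations_``
    (descending, clipped to [0, 1]), ``x_variable_correlations_`` /
    ``y_variable_correlations_`` (per variable, r with the two plotting
    variates).  Variable correlations are taken against Gram-Schmidt
    orthogonalized score pairs so every biplot point lies inside the unit
    circle even under ridge regularization.
    """

    def __init__(self, n_components: int = 2, ridge: float = 0.1):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, Y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, dtype=float))
        if len(Xdf) != len(Ydf):
            raise ValueError("X and Y must contain the same samples")
        if len(Xdf) < 3:
            raise ValueError("need >= 3 samples")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        Xs, keep_x = _standardize(Xdf.to_numpy(dtype=float))
        Ys, keep_y = _standardize(Ydf.to_numpy(dtype=float))
        for keep, df, block in ((keep_x, Xdf, "X"), (keep_y, Ydf, "Y")):
            if not keep.all():
                dropped = [str(c) for c, k in zip(df.columns, keep) if not k]
                warnings.warn(f"dropping constant {block} column(s): {dropped}", stacklevel=2)
        self.x_names_ = [str(c) for c, k in zip(Xdf.columns, keep_x) if k]
        self.y_names_ = [str(c) for c, k in zip(Ydf.columns, keep_y) if k]

        n = Xs.shape[0]
        Cxx = Xs.T @ Xs / (n - 1) + self.ridge * np.eye(Xs.shape[1])
        Cyy = Ys.T @ Ys / (n - 1) + self.ridge * np.eye(Ys.shape[1])
        Cxy = Xs.T @ Ys / (n - 1)
        # whitened cross-covariance; SVD gives the canonical structure
        Lx = linalg.cholesky(Cxx, lower=True)
        Ly = linalg.cholesky(Cyy, lower=True)
        K = linalg.solve_triangular(Lx, Cxy, lower=True)
        K = linalg.solve_triangular(Ly, K.T, lower=True).T
        U, svals, Vt = linalg.svd(K, full_matrices=False)
        k = min(self.n_components, svals.size)
        self.canonical_correlations_ = np.clip(svals[:k], 0.0, 1.0)
        A = linalg.solve_triangular(Lx.T, U[:, :k], lower=False)
        B = linalg.solve_triangular(Ly.T, Vt.T[:, :k], lower=False)
        self.x_weights_ = A
        self.y_weights_ = B
        self.x_scores_ = Xs @ A
        self.y_scores_ = Ys @ B

        self.x_variable_correlations_ = self._variable_corr(Xs, self.x_scores_)
        self.y_variable_correlations_ = self._variable_corr(Ys, self.y_scores_)
        return self

    @staticmethod
    def _variable_corr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
        # orthonormalize the score pair (QR) before correlating, so the
        # per-variable (r1, r2) vector is an R^2 decomposition and stays
        # inside the unit circle
        Q, _ = np.linalg.qr(scores - scores.mean(axis=0))
        bc = block - block.mean(axis=0)
        norms = np.linalg.norm(bc, axis=0)
        norms[norms == 0] = 1.0
        return (bc / norms).T @ Q

    def variable_correlation_table(self) -> pd.DataFrame:
        check_is_fitted(self, "x_weights_")
        rows = []
        for names, corr, block in (
            (self.x_names_, self.x_variable_correlations_, "X"),
            (self.y_names_, self.y_variable_correlations_, "Y"),
        ):
            for name, (r1, r2) in zip(names, corr):
                rows.append((name, block, float(r1), float(r2)))
        return pd.DataFrame(rows, columns=["variable", "block", "r1", "r2"])


def canonical_regression(X, Y, ridge: float = 0.1, n_components: int = 2) -> RidgeCCA:
    """Functional surface over :class:`RidgeCCA` (metabolites as X, panel as Y)."""
    if isinstance(X, ConcentrationTable):
        X = X.values
    return RidgeCCA(n_components=n_components, ridge=ridge).fit(X, Y)


# ---------------------------------------------------------------------------
# correlation networks

def build_network(
    c: ConcentrationTable,
    stats: pd.DataFrame | None = None,
    threshold: float = 0.6,
) -> nx.MultiGraph:
    """Thresholded Pearson correlation network of metabolites.

    Nodes carry ``log2fc`` and ``star`` copied from a per-metabolite stats
    table (index = metabolite) when provided; edges with ``kind="pearson"``
    carry ``r``, ``abs_r`` (width) and ``sign``.  Constant metabolites are
    excluded (r undefined) with a warning.
    """
    V = c.values
    if len(V) < 4:
        raise ValueError(f"need >= 4 samples, got {len(V)}")
    sd = V.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"excluding constant metabolite(s): {constant}", stacklevel=2)
        V = V.drop(columns=constant)
    names = list(V.columns)
    net = nx.MultiGraph(threshold=float(threshold))
    for m in names:
        attrs = {}
        if stats is not None and m in stats.index:
            attrs["log2fc"] = float(stats.loc[m, "log2fc"])
            attrs["star"] = str(stats.loc[m, "star"])
        net.add_node(m, **attrs)
    R = np.corrcoef(V.to_numpy(dtype=float), rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(R[i, j])
            if abs(r) >= threshold:
                net.add_edge(
                    names[i], names[j], key="pearson",
                    kind="pearson", r=r, abs_r=abs(r), sign=int(np.sign(r)),
                )
    return net


def load_default_reactions() -> pd.DataFrame:
    """Packaged curated biochemical-reaction pairs among the library metabolites."""
    p = Path(str(resources.files("fibromet.data").joinpath("reactions.tsv")))
    return pd.read_csv(p, sep="\t")


def _synonym_map() -> dict[str, str]:
    p = Path(str(resources.files("fibromet.data").joinpath("synonyms.tsv")))
    df = pd.read_csv(p, sep="\t")
    return dict(zip(df["synonym"].str.lower(), df["canonical"]))


def overlay_reactions(
    net: nx.MultiGraph,
    reactions: pd.DataFrame | str | Path | None = None,
) -> nx.MultiGraph:
    """Add known-reaction edges (``kind="reaction"``, no r) to a network.

    Reaction endpoint names are resolved case-insensitively with a synonym
    map; pairs with an unresolvable endpoint are skipped and logged via a
    warning.  Pearson edges are untouched; duplicate reaction pairs are
    deduplicated.
    """
    if reactions is None:
        reactions = load_default_reactions()
    elif not isinstance(reactions, pd.DataFrame):
        reactions = pd.read_csv(reactions, sep="\t")
    if not {"metabolite_a", "metabolite_b"} <= set(reactions.columns):
        raise ValueError("reaction list needs columns metabolite_a, metabolite_b")
    syn = _synonym_map()
    by_lower = {str(n).lower(): n for n in net.nodes}

    def resolve(name: str):
        low = str(name).strip().lower()
        low = syn.get(low, low).lower() if low in syn else low
        return by_lower.get(low)

    out = net.copy()
    unresolved = []
    seen: set[frozenset] = set()
    for row in reactions.itertuples(index=False):
        u, v = resolve(row.metabolite_a), resolve(row.metabolite_b)
        if u is None or v is None or u == v:
            unresolved.append((row.metabolite_a, row.metabolite_b))
            continue
        pair = frozenset((u, v))
        if pair in seen:
            continue
        seen.add(pair)
        out.add_edge(u, v, key="reaction", kind="reaction")
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} reaction pair(s) had unresolvable endpoints",
            stacklevel=2,
        )
    return out


def write_network(net: nx.MultiGraph, path: str | Path, fmt: str | None = None) -> None:
    """Export to GraphML or GML (inferred from the file suffix)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "gml":
        nx.write_gml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
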