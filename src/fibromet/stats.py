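"""Univariate group comparisons per metabolite.

For each metabolite and contrast (group_a vs group_b): Shapiro-Wilk
normality on each group gates the choice between a two-sided Welch t-test
and the Wilcoxon rank-sum (Mann-Whitney) test; the effect is the log2
ratio of group means; p-values are corrected across metabolites per
contrast with Benjamini-Hochberg, and the adjusted q is encoded as the
usual significance stars (*** < 0.001, ** < 0.01, * < 0.05).

Welch's unequal-variance form is used deliberately: it is safer than the
pooled-variance t-test under heteroscedasticity and has the same null
behavior when variances are equal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import ConcentrationTable

__all__ = ["compare_groups", "bh_adjust", "star_code", "stats_table", "write_stats_html"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def star_code(q: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def _one_metabolite(a: np.ndarray, b: np.ndarray, alpha_normality: float) -> tuple[float, str]:
    """Raw p and test used for one metabolite, one contrast."""
    # Shapiro-Wilk needs non-constant input; constant groups go to the rank test
    def _normal(x):
        if np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue >= alpha_normality

    if _normal(a) and _normal(b):
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
        return float(p), "t"
    p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(p), "rank"


def compare_groups(
    c: ConcentrationTable,
    annotations: pd.DataFrame,
    contrast: tuple[str, str],
    alpha_normality: float = 0.05,
    fold_change: str = "arithmetic",
) -> pd.DataFrame:
    """Per-metabolite stats for one contrast ``(group_a, group_b)``.

    Returns a DataFrame indexed by metabolite with columns ``log2fc``,
    ``p_raw``, ``q_bh``, ``test_used``, ``star``; log2fc = log2(mean_a /
    mean_b) (or of geometric means with ``fold_change="geometric"``).
    Metabolites with a non-positive group mean get NaN log2fc and are
    flagged in the ``flag`` column.
    """
    group_a, group_b = contrast
    for g in contrast:
        n = (annotations["group"] == g).sum()
        if n < 3:
            raise ValueError(f"group {g!r} has {n} samples; need >= 3")
    A = c.group_values(annotations, group_a)
    B = c.group_values(annotations, group_b)
    rows = []
    for m in c.values.columns:
        a = A[m].to_numpy(dtype=float)
        b = B[m].to_numpy(dtype=float)
        if fold_change == "arithmetic":
            ma, mb = a.mean(), b.mean()
        elif fold_change == "geometric":
            ma = np.exp(np.log(a).mean()) if np.all(a > 0) else np.nan
            mb = np.exp(np.log(b).mean()) if np.all(b > 0) else np.nan
        else:
            raise ValueError(f"unknown fold_change {fold_change!r}")
        flag = ""
        if not (ma > 0 and mb > 0):
            lfc = np.nan
            flag = "non-positive group mean"
        else:
            lfc = float(np.log2(ma / mb))
        p, test = _one_metabolite(a, b, alpha_normality)
        rows.append((m, lfc, p, test, flag))
    out = pd.DataFrame(
        rows, columns=["metabolite", "log2fc", "p_raw", "test_used", "flag"]
    ).set_index("metabolite")
    out["q_bh"] = bh_adjust(out["p_raw"].to_numpy())
    out["star"] = [star_code(q) for q in out["q_bh"]]
    out["contrast"] = f"{group_a}/{group_b}"
    return out[["log2fc", "p_raw", "q_bh", "test_used", "star", "flag", "contrast"]]


def stats_table(
    c: ConcentrationTable,
    annotations: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    alpha_normality: float = 0.05,
    fold_change: str = "arithmetic",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All contrasts side by side.

    Returns ``(compact, full)``: the compact table mirrors the published
    layout (per contrast: log2fc + star columns); the full table stacks
    every numeric column per contrast.
    """
    pieces = {}
    for contrast in contrasts:
        pieces[f"{contrast[0]}/{contrast[1]}"] = compare_groups(
            c, annotations, contrast, alpha_normality, fold_change
        )
    full = pd.concat(pieces.values())
    compact = pd.DataFrame(index=next(iter(pieces.values())).index)
    for label, tab in pieces.items():
        compact[f"log2fc {label}"] = tab["log2fc"].round(2)
        compact[f"star {label}"] = tab["star"]
    return compact, full


def write_stats_html(compact: pd.DataFrame, path) -> None:
    """Minimal colored fold-change table (red up, blue down, stars shown)."""
    fc_cols = [c for c in compact.columns if c.startswith("log2fc")]
    vmax = max(1e-9, np.nanmax(np.abs(compact[fc_cols].to_numpy(dtype=float))))
    rows = ["<table border='1' style='border-collapse:collapse;font-family:sans-serif'>"]
    header = "".join(f"<th>{c}</th>" for c in compact.columns)
    rows.append(f"<tr><th>metabolite</th>{header}</tr>")
    for m, row in compact.iterrows():
        cells = []
        for col in compact.columns:
            v = row[col]
            if col.startswith("log2fc") and pd.notna(v):
                x = float(v) / vmax
                col_css = (
                    f"background-color: rgba(214,47,39,{abs(x):.2f})"
                    if x > 0
                    else f"background-color: rgba(59,76,192,{abs(x):.2f})"
                )
                cells.append(f"<td style='{col_css}'>{v}</td>")
            else:
                cells.append(f"<td>{'' if pd.isna(v) else v}</td>")
        rows.append(f"<tr><td>{m}</td>{''.join(cells)}</tr>")
    rows.append("</table>")
    with open(path, "w") as fh:
        fh.write("\n".join(rows))
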