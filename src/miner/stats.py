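"""Differential expression / activity statistics.

Two-group comparisons per gene (or driver): Welch t-test or Wilcoxon
rank-sum, Benjamini-Hochberg FDR, and a signed z-score derived from the
two-sided p-value (z = Phi^-1(1 - p/2), signed by the fold-change
direction) so that effect direction and significance compose into a single
number downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["z_from_p", "differential", "DIFFERENTIAL_METHODS"]

DIFFERENTIAL_METHODS = ("t.test", "wilcoxon")


def z_from_p(p: float, direction_sign: float) -> float:
    """Signed z from a two-sided p-value: ``sign * Phi^-1(1 - p/2)``."""
    p = float(p)
    if p <= 0:
        raise ValueError("p must be in (0, 1]")
    if p < np.finfo(float).tiny:
        warnings.warn("p underflow; clamped at the smallest positive float")
        p = np.finfo(float).tiny
    if p >= 1.0:
        return 0.0
    return float(np.sign(direction_sign) * stats.norm.isf(p / 2.0))


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def differential(values, group1, group2, method: str = "t.test",
                 value_type: str = "expression",
                 feature_names=None) -> pd.DataFrame:
    """Per-feature two-group differential statistics.

    Parameters
    ----------
    values
        features x cells matrix (expression on the log2 scale, or activity),
        or a DataFrame indexed by feature.
    group1, group2
        Disjoint cell index arrays (or boolean masks), each with >= 2 cells.
    method
        ``"t.test"`` (Welch, two-sided) or ``"wilcoxon"`` (rank-sum).
    value_type
        ``"expression"``: log2FC is a difference of log2 means and the pct
        columns count non-zero cells. ``"activity"``: the fold-change column
        is a raw difference of means and pct counts non-NA cells.

    Returns a DataFrame with log2FC, p_value, fdr, z, pct_group1, pct_group2.
    """
    if method not in DIFFERENTIAL_METHODS:
        raise ValueError(f"method must be one of {DIFFERENTIAL_METHODS}")
    if isinstance(values, pd.DataFrame):
        feature_names = values.index.to_numpy()
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        if feature_names is None:
            feature_names = np.array([f"f{i}" for i in range(X.shape[0])])

    def as_idx(g):
        g = np.asarray(g)
        return np.where(g)[0] if g.dtype == bool else g

    g1, g2 = as_idx(group1), as_idx(group2)
    if len(set(g1) & set(g2)):
        raise ValueError("groups overlap")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 cells")

    A, B = X[:, g1], X[:, g2]
    lfc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    pvals = np.ones(X.shape[0])
    for i in range(X.shape[0]):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if a.size < 2 or b.size < 2 or (np.std(a) == 0 and np.std(b) == 0):
            pvals[i] = 1.0
            continue
        if method == "t.test":
            pvals[i] = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            pvals[i] = stats.mannwhitneyu(a, b,
                                          alternative="two-sided").pvalue
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    fdr = _bh_fdr(pvals)
    z = np.array([z_from_p(p, s) for p, s in zip(pvals, np.sign(lfc))])
    if value_type == "activity":
        pct1 = (~np.isnan(A)).mean(axis=1)
        pct2 = (~np.isnan(B)).mean(axis=1)
    else:
        pct1 = (np.nan_to_num(A) != 0).mean(axis=1)
        pct2 = (np.nan_to_num(B) != 0).mean(axis=1)
    return pd.DataFrame({
        "log2FC": lfc, "p_value": pvals, "fdr": fdr, "z": z,
        "pct_group1": pct1, "pct_group2": pct2, "method": method,
        "value_type": value_type,
    }, index=pd.Index(feature_names, name="feature"))
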