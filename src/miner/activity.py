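"""Driver activity: regulon-averaged, column-z-normalized expression.

A driver's activity in a cell is a mean of its targets' z-normalized
expression in that cell — the idea being that a regulator's functional
output shows in its targets even when its own transcript does not change
(hidden drivers). Four means are supported: plain, MI-weighted and
Spearman-signed, absolute, and the larger-magnitude of the positive-target
and negative-target means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .network import Regulon, to_regulons

ACTIVITY_METHODS = ("mean", "weightedmean", "absmean", "maxmean")


def z_normalize_columns(m) -> np.ndarray:
    """Z-normalize each cell (column) across genes: (x - cell mean) / cell sd.

    Sample (n-1) standard deviation, the R ``scale()`` convention; constant
    cells map to zeros. Accepts an ExpressionMatrix (genes x cells) or a
    genes x cells array and returns a dense genes x cells array.
    """
    from .expression import ExpressionMatrix

    X = m.dense() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes to z-normalize cells")
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return Z


def regulon_activity(Z: np.ndarray, gene_names, regulon: Regulon,
                     method: str = "mean",
                     weights: dict | None = None) -> np.ndarray:
    """Per-cell activity of one driver from z-normalized expression.

    Parameters
    ----------
    Z
        genes x cells z-normalized matrix.
    weights
        target -> (mi, sign); required for ``weightedmean``.

    Returns the per-cell activity vector, or all-NaN when no target of the
    regulon is present in ``gene_names``.
    """
    if method not in ACTIVITY_METHODS:
        raise ValueError(f"unknown method {method!r}")
    name_to_idx = {g: i for i, g in enumerate(np.asarray(gene_names))}
    pos = [t for t in regulon.positive if t in name_to_idx]
    neg = [t for t in regulon.negative if t in name_to_idx]
    dropped = len(regulon.targets) - len(pos) - len(neg)
    if dropped:
        warnings.warn(f"{regulon.driver}: {dropped} targets absent from matrix")
    if not pos and not neg:
        return np.full(Z.shape[1], np.nan)
    idx = np.array([name_to_idx[t] for t in pos + neg])
    T = Z[idx]  # targets x cells

    if method == "mean":
        return T.mean(axis=0)
    if method == "absmean":
        return np.abs(T).mean(axis=0)
    if method == "weightedmean":
        if weights is None:
            raise ValueError("weightedmean requires MI/sign weights")
        w = np.array([weights[t][0] * weights[t][1] for t in pos + neg])
        return (w[:, None] * T).sum(axis=0) / np.abs(w).sum()
    # maxmean: the larger-magnitude of the positive- and negative-target means
    means = []
    if pos:
        means.append(T[: len(pos)].mean(axis=0))
    if neg:
        means.append(T[len(pos):].mean(axis=0))
    if len(means) == 1:
        return means[0]
    stacked = np.vstack(means)
    pick = np.argmax(np.abs(stacked), axis=0)
    return stacked[pick, np.arange(Z.shape[1])]


def _weights_from_network(net: pd.DataFrame) -> dict:
    out: dict = {}
    for row in net.itertuples():
        out.setdefault(row.source, {})[row.target] = (row.mi, row.sign)
    return out


def activity_from_network(Z: np.ndarray, gene_names, net: pd.DataFrame,
                          method: str = "mean"):
    """Activity of every hub in an annotated network; returns (drivers, matrix)."""
    regulons = to_regulons(net)
    weights = _weights_from_network(net) if method == "weightedmean" else {}
    drivers = sorted(regulons)
    rows = [regulon_activity(Z, gene_names, regulons[d], method,
                             weights.get(d)) for d in drivers]
    return drivers, np.vstack(rows) if rows else np.empty((0, Z.shape[1]))


def activity_in_batch(m, networks: dict, labels, method: str = "mean") -> pd.DataFrame:
    """Cluster-wise activity with global min-non-NA imputation.

    Each cluster's cells are z-normalized on their own, activities are
    computed from that cluster's network, the per-cluster blocks are
    concatenated (drivers x cells), and any NA — a driver absent from some
    cluster's network — is imputed with the minimum non-NA activity of the
    merged matrix.
    """
    from .expression import ExpressionMatrix

    X = m.dense() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    barcodes = (m.cell_barcodes if isinstance(m, ExpressionMatrix)
                else np.arange(X.shape[1]))
    gene_names = (m.gene_ids if isinstance(m, ExpressionMatrix)
                  else np.array([f"g{i}" for i in range(X.shape[0])]))
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels), key=str)
    missing = [c for c in clusters if c not in networks]
    if missing:
        raise ValueError(f"clusters without a network: {missing}")

    all_drivers = sorted({d for c in clusters
                          for d in networks[c]["source"].unique()})
    out = np.full((len(all_drivers), X.shape[1]), np.nan)
    driver_idx = {d: i for i, d in enumerate(all_drivers)}
    for c in clusters:
        cols = np.where(labels == c)[0]
        Z = z_normalize_columns(X[:, cols])
        drivers, act = activity_from_network(Z, gene_names, networks[c], method)
        for d, row in zip(drivers, act):
            out[driver_idx[d], cols] = row
    if np.isnan(out).any():
        if np.isnan(out).all():
            raise ValueError("no activity computable for any driver")
        out = np.where(np.isnan(out), np.nanmin(out), out)
    return pd.DataFrame(out, index=all_drivers, columns=barcodes)


def top_n_restricted_activity(m, networks: dict, driver: str,
                              method: str = "mean") -> dict:
    """Cross-method comparison: truncate a driver's regulon to its top-MI
    n_i targets, where n_i is the smallest regulon size among the compared
    networks, then compute activity per network.

    Returns network-name -> per-cell activity vector.
    """
    from .expression import ExpressionMatrix

    if len(networks) < 2:
        raise ValueError("need at least two networks to compare")
    X = m.dense() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    gene_names = (m.gene_ids if isinstance(m, ExpressionMatrix)
                  else np.array([f"g{i}" for i in range(X.shape[0])]))
    sizes = {}
    for name, net in networks.items():
        sub = net[net["source"] == driver]
        if sub.empty:
            warnings.warn(f"driver {driver} missing from network {name!r}; skipped")
            return {}
        sizes[name] = len(sub)
    n_min = min(sizes.values())
    Z = z_normalize_columns(X)
    out = {}
    for name, net in networks.items():
        sub = net[net["source"] == driver].nlargest(n_min, "mi")
        reg = to_regulons(sub)[driver]
        out[name] = regulon_activity(Z, gene_names, reg, method,
                                     _weights_from_network(sub).get(driver))
    return out


class RegulonActivity(TransformerMixin, BaseEstimator):
    """Transform expression into driver activity via an inferred network.

    Parameters
    ----------
    network : annotated edge table (as produced by
        :class:`~miner.network.SJARACNe`), or dict cluster -> table for
        batch mode.
    method : {"mean", "weightedmean", "absmean", "maxmean"}
    labels : cluster label per cell (batch mode only).

    ``transform(X)`` takes cells x genes expression and returns a
    cells x drivers activity array; ``drivers_`` names the columns.
    """

    def __init__(self, network=None, method: str = "mean", labels=None):
        self.network = network
        self.method = method
        self.labels = labels

    def fit(self, X, y=None, feature_names=None):
        if self.network is None:
            raise ValueError("network must be provided")
        if isinstance(self.network, dict):
            self.drivers_ = sorted({d for net in self.network.values()
                                    for d in net["source"].unique()})
        else:
            self.drivers_ = sorted(self.network["source"].unique())
        return self

    def transform(self, X, feature_names=None):
        from .expression import ExpressionMatrix

        if not hasattr(self, "drivers_"):
            self.fit(X)
        if isinstance(X, ExpressionMatrix):
            G = X.dense()
            feature_names = X.gene_ids
        elif isinstance(X, pd.DataFrame):
            feature_names = X.columns.to_numpy()
            G = X.to_numpy(dtype=float).T
        else:
            G = np.asarray(X, dtype=float).T  # genes x cells
            if feature_names is None:
                feature_names = np.array([f"g{i}" for i in range(G.shape[0])])
        if isinstance(self.network, dict):
            if self.labels is None:
                raise ValueError("batch mode needs per-cell labels")
            df = activity_in_batch(G, self.network, self.labels, self.method)
            df.index = pd.Index(self.drivers_)
            return df.to_numpy().T
        Z = z_normalize_columns(G)
        drivers, act = activity_from_network(Z, feature_names, self.network,
                                             self.method)
        self.drivers_ = drivers
        return act.T
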