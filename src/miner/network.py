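"""Hub-constrained signed regulatory network inference.

ARACNe-family pipeline specialised to driver (TF / signaling) hubs:

1. optional metacell aggregation (k-means micro-clusters on a PCA of the
   normalized matrix, averaged per micro-cluster) to mitigate dropout;
2. adaptive-partitioning MI for every hub x gene pair;
3. an MI significance threshold calibrated on a permutation null
   (exponential tail fit), default per-edge p-value ``pb = 1e-7``;
4. a Data Processing Inequality (DPI) tolerance filter removing the weakest
   edge of every fully connected triangle (likely indirect);
5. a bootstrap consensus: ``n_boot`` cell resamples, per-edge occurrence
   counts tested against a Poisson null, retained at ``pc = 1e-2``;
6. correlation annotation (Spearman / Pearson / regression slope), with the
   Spearman sign splitting each regulon into positive and negative targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit, prange
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .mi import AdaptiveMIConfig, _adaptive_mi_ranks, _rank_uniform, adaptive_mi_pairs

__all__ = [
    "NetworkConfig",
    "MetaCellConfig",
    "metacell_aggregate",
    "calibrate_mi_null",
    "dpi_filter",
    "infer_single_network",
    "bootstrap_consensus",
    "annotate_network",
    "to_regulons",
    "Regulon",
    "SJARACNe",
]


@dataclass
class NetworkConfig:
    """SJARACNe-style inference settings (defaults follow the published pipeline)."""

    hubs: list = field(default_factory=list)
    pb: float = 1e-7
    dpi_tolerance: float = 0.0
    n_boot: int = 100
    pc: float = 1e-2
    seed: int = 0
    null_pairs: int = 100_000
    mi_config: AdaptiveMIConfig = field(default_factory=AdaptiveMIConfig)

    def __post_init__(self) -> None:
        if not (0 < self.pb < 1 and 0 < self.pc < 1):
            raise ValueError("pb and pc must be in (0, 1)")
        if not 0 <= self.dpi_tolerance <= 1:
            raise ValueError("dpi_tolerance must be in [0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class MetaCellConfig:
    """Metacell aggregation: ``gamma`` cells per metacell on ``n_pc`` PCs."""

    gamma: int = 20
    n_pc: int = 10

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")


@dataclass
class Regulon:
    """A driver and its signed target sets."""

    driver: str
    positive: list
    negative: list

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"targets in both signs: {sorted(overlap)}")

    @property
    def targets(self) -> list:
        return list(self.positive) + list(self.negative)


def metacell_aggregate(m, cfg: MetaCellConfig | None = None, seed: int = 0):
    """Aggregate similar cells into metacell pseudobulk profiles.

    Micro-clusters are k-means (k = ceil(cells / gamma)) on the top ``n_pc``
    principal components of the normalized matrix; each metacell is the mean
    profile of its member cells.
    """
    from .expression import ExpressionMatrix

    cfg = cfg or MetaCellConfig()
    is_em = isinstance(m, ExpressionMatrix)
    X = m.dense().T if is_em else np.asarray(m, dtype=float)  # cells x genes
    n_cells = X.shape[0]
    if cfg.gamma > n_cells:
        raise ValueError(f"gamma={cfg.gamma} exceeds {n_cells} cells")
    k = int(np.ceil(n_cells / cfg.gamma))
    if k >= n_cells:
        members = np.arange(n_cells)
    else:
        n_pc = min(cfg.n_pc, min(X.shape) - 1)
        pcs = PCA(n_components=n_pc, svd_solver="full",
                  random_state=seed).fit_transform(X)
        members = KMeans(n_clusters=k, n_init=1, random_state=seed,
                         max_iter=300).fit_predict(pcs)
        members = _force_k_clusters(members, k)
    labels = np.unique(members)
    profiles = np.vstack([X[members == c].mean(axis=0) for c in labels])
    if is_em:
        return ExpressionMatrix(
            values=profiles.T,
            gene_ids=m.gene_ids,
            gene_symbols=m.gene_symbols,
            cell_barcodes=[f"metacell_{c}" for c in range(profiles.shape[0])],
            value_kind=m.value_kind,
        ), members
    return profiles, members


def _force_k_clusters(members: np.ndarray, k: int) -> np.ndarray:
    """Split the largest clusters until exactly k are non-empty (degenerate
    inputs, e.g. exact duplicate cells, can collapse k-means clusters)."""
    members = members.copy()
    next_label = members.max() + 1
    while len(np.unique(members)) < k:
        values, counts = np.unique(members, return_counts=True)
        big = values[np.argmax(counts)]
        idx = np.where(members == big)[0]
        members[idx[: len(idx) // 2]] = next_label
        next_label += 1
    return members


@njit(cache=True, parallel=True)
def _null_mi_kernel(R, pair_i, pair_j, seeds, chi2_crit, min_points, out):
    n = R.shape[1]
    for p in prange(pair_i.size):
        ry = R[pair_j[p]].copy()
        state = np.uint64(seeds[p])
        # Fisher-Yates shuffle driven by an LCG so each pair is independent
        for t in range(n - 1, 0, -1):
            state = state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
            u = float(state >> np.uint64(11)) / 9007199254740992.0
            s = int(u * (t + 1))
            tmp = ry[t]
            ry[t] = ry[s]
            ry[s] = tmp
        out[p] = _adaptive_mi_ranks(R[pair_i[p]], ry, chi2_crit, min_points)


def null_mi_sample(X: np.ndarray, n_pairs: int, seed: int = 0,
                   mi_config: AdaptiveMIConfig | None = None,
                   ranks: np.ndarray | None = None) -> np.ndarray:
    """Adaptive MI on ``n_pairs`` randomly chosen, randomly permuted gene pairs."""
    mi_config = mi_config or AdaptiveMIConfig()
    R = _rank_uniform(np.asarray(X, dtype=float)) if ranks is None else ranks
    rng = np.random.default_rng(seed)
    n_genes = R.shape[0]
    pair_i = rng.integers(0, n_genes, size=n_pairs)
    pair_j = rng.integers(0, n_genes, size=n_pairs)
    seeds = rng.integers(1, 2**62, size=n_pairs, dtype=np.uint64)
    out = np.empty(n_pairs)
    crit = stats.chi2.isf(mi_config.alpha, df=3)
    _null_mi_kernel(R, pair_i, pair_j, seeds, crit, mi_config.min_points, out)
    return out


def mi_threshold_from_null(null_mi: np.ndarray, pb: float,
                           tail_fraction: float = 0.05,
                           min_tail_points: int = 10) -> float:
    """MI cutoff at per-edge p-value ``pb`` from a permutation-null sample.

    Fits an exponential tail, ``ln p = a + b * MI``, to the empirical upper
    tail of the null and inverts it at ``pb``. The adaptive estimator
    returns exactly 0 for most independent pairs (the root cell passes the
    uniformity test and is never split), so the informative tail is the
    strictly positive part of the null, capped at ``tail_fraction``; at
    least ``min_tail_points`` positive draws are required.
    """
    null_mi = np.sort(np.asarray(null_mi))[::-1]
    n = null_mi.size
    n_tail = min(int(np.ceil(tail_fraction * n)), int((null_mi > 0).sum()))
    if n_tail < min_tail_points:
        raise ValueError(
            f"only {n_tail} positive null MI draws; increase null_pairs "
            "to resolve the null tail"
        )
    tail = null_mi[:n_tail]
    emp_p = (np.arange(1, n_tail + 1)) / n
    b, a = np.polyfit(tail, np.log(emp_p), 1)
    if b >= 0:
        raise ValueError(
            "degenerate null tail fit (non-negative slope); "
            "increase null_pairs or check the input matrix"
        )
    return float((np.log(pb) - a) / b)


def calibrate_mi_null(X, cfg: NetworkConfig, ranks=None) -> float:
    """Permutation-null MI threshold at the configured ``pb``."""
    if cfg.null_pairs < 100:
        raise ValueError("need at least 100 null pairs")
    null = null_mi_sample(X, cfg.null_pairs, seed=cfg.seed + 104729,
                          mi_config=cfg.mi_config, ranks=ranks)
    return mi_threshold_from_null(null, cfg.pb)


def dpi_filter(edges: dict, tolerance: float = 0.0) -> dict:
    """Data Processing Inequality filter over fully connected triangles.

    ``edges`` maps unordered node pairs ``(a, b)`` (a < b canonical order) to
    MI. For every triangle present in the input edge set, the minimum-MI edge
    is removed when ``mi_min < min(other two) * (1 - tolerance)``. Removals
    are decided simultaneously against the original edge set.
    """
    neighbors: dict = {}
    for (a, b) in edges:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    to_remove = set()
    for (a, b), mi_ab in edges.items():
        for c in neighbors.get(a, set()) & neighbors.get(b, set()):
            mi_ac = edges[tuple(sorted((a, c)))]
            mi_bc = edges[tuple(sorted((b, c)))]
            if mi_ab < min(mi_ac, mi_bc) * (1.0 - tolerance):
                to_remove.add((a, b))
                break
    return {k: v for k, v in edges.items() if k not in to_remove}


def infer_single_network(X: np.ndarray, hub_idx: np.ndarray,
                         mi_threshold: float, cfg: NetworkConfig,
                         ranks: np.ndarray | None = None) -> dict:
    """One MI network: adaptive MI on every hub x gene pair, thresholded, DPI-filtered.

    ``X`` is genes x samples; ``hub_idx`` indexes hub rows. Returns a dict
    mapping canonical (min, max) gene-index pairs to MI.
    """
    n_genes = X.shape[0] if ranks is None else ranks.shape[0]
    hub_set = set(int(h) for h in hub_idx)
    pairs = []
    for h in sorted(hub_set):
        for g in range(n_genes):
            if g == h:
                continue
            if g in hub_set and g < h:
                continue  # unordered hub-hub pair already covered
            pairs.append((h, g))
    pairs = np.asarray(pairs, dtype=np.int64)
    mi = adaptive_mi_pairs(X, pairs, cfg=cfg.mi_config, ranks=ranks)
    keep = mi >= mi_threshold
    edges = {tuple(sorted(map(int, pairs[i]))): float(mi[i])
             for i in np.where(keep)[0]}
    return dpi_filter(edges, cfg.dpi_tolerance)


def bootstrap_consensus(X: np.ndarray, hub_idx: np.ndarray,
                        mi_threshold: float, cfg: NetworkConfig) -> pd.DataFrame:
    """Poisson consensus over ``n_boot`` cell-resampled networks.

    Support is the number of bootstrap networks containing an edge; the
    Poisson rate is the mean occurrence count over all distinct observed
    edges, and edges are kept at upper-tail ``P(X >= support) <= pc``.
    """
    X = np.asarray(X, dtype=float)
    n_samples = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    support: dict = {}
    mi_sum: dict = {}
    for _ in range(cfg.n_boot):
        take = rng.integers(0, n_samples, size=n_samples)
        ranks = _rank_uniform(X[:, take])
        net = infer_single_network(X, hub_idx, mi_threshold, cfg, ranks=ranks)
        for e, mi in net.items():
            support[e] = support.get(e, 0) + 1
            mi_sum[e] = mi_sum.get(e, 0.0) + mi
    if not support:
        warnings.warn("no edge detected in any bootstrap; empty network")
        return pd.DataFrame(columns=["source_idx", "target_idx", "mi",
                                     "support", "p_consensus"])
    counts = np.array(list(support.values()))
    lam = counts.sum() / len(support)
    rows = []
    for e, cnt in support.items():
        p_cons = float(stats.poisson.sf(cnt - 1, lam))
        if p_cons <= cfg.pc:
            rows.append((e[0], e[1], mi_sum[e] / cnt, cnt, p_cons))
    df = pd.DataFrame(rows, columns=["source_idx", "target_idx", "mi",
                                     "support", "p_consensus"])
    return df.sort_values("mi", ascending=False, kind="stable",
                          ignore_index=True)


def annotate_network(net: pd.DataFrame, X: np.ndarray,
                     gene_names, hub_set) -> pd.DataFrame:
    """Add correlation statistics and orient edges hub -> target.

    Spearman/Pearson correlations, the least-squares slope of target on
    source and the Pearson p-value are computed on the inference matrix;
    ``sign`` is the sign of the Spearman correlation.
    """
    gene_names = np.asarray(gene_names)
    rows = []
    for _, edge in net.iterrows():
        a, b = int(edge.source_idx), int(edge.target_idx)
        # orient from a hub; canonical order for hub-hub pairs
        src, tgt = (a, b) if a in hub_set else (b, a)
        x, y = X[src], X[tgt]
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"constant gene in edge ({gene_names[src]}, "
                f"{gene_names[tgt]}); correlations set to 0")
            spear = pear = slope = 0.0
            p_corr = 1.0
        else:
            spear = float(stats.spearmanr(x, y).statistic)
            pr = stats.pearsonr(x, y)
            pear, p_corr = float(pr.statistic), float(pr.pvalue)
            slope = float(np.polyfit(x, y, 1)[0])
        rows.append({
            "source": gene_names[src], "target": gene_names[tgt],
            "mi": edge.mi, "pearson": pear, "spearman": spear,
            "slope": slope, "p_correlation": p_corr,
            "sign": int(np.sign(spear)),
            "support": int(edge.support), "p_consensus": edge.p_consensus,
        })
    return pd.DataFrame(rows, columns=["source", "target", "mi", "pearson",
                                       "spearman", "slope", "p_correlation",
                                       "sign", "support", "p_consensus"])


def to_regulons(net: pd.DataFrame) -> dict[str, Regulon]:
    """Split each hub's targets by correlation sign into a Regulon."""
    regulons = {}
    for driver, sub in net.groupby("source", sort=True):
        pos = sub.loc[sub["sign"] >= 0, "target"].tolist()
        neg = sub.loc[sub["sign"] < 0, "target"].tolist()
        if (sub["sign"] == 0).any():
            warnings.warn(f"{driver}: zero-sign targets assigned to positive set")
        regulons[str(driver)] = Regulon(str(driver), pos, neg)
    return regulons


class SJARACNe(BaseEstimator):
    """Signed hub-constrained consensus network inference.

    Parameters
    ----------
    hubs : list of str
        Driver gene names (TFs or signaling genes); must be present among
        ``feature_names`` at fit time (missing hubs are dropped with a
        warning).
    pb : float
        Per-edge MI p-value threshold (permutation-null calibrated).
    dpi_tolerance : float
        DPI tolerance in [0, 1]; 0 removes every dominated triangle edge.
    n_boot : int
        Bootstrap count for the consensus network.
    pc : float
        Poisson consensus p-value threshold.
    null_pairs : int
        Permuted gene pairs used to calibrate the MI null.
    metacell_gamma : int or None
        If set, aggregate cells into metacells of ~gamma cells first.
    metacell_n_pc : int
        PCA dimensions for metacell micro-clustering.
    alpha, min_points : adaptive-MI quadrant-split test settings.
    random_state : int
        Seed for null calibration, metacells and bootstraps.

    Attributes
    ----------
    network_ : annotated consensus edge table (source, target, mi, pearson,
        spearman, slope, p_correlation, sign, support, p_consensus).
    regulons_ : dict driver -> :class:`Regulon`.
    mi_threshold_ : calibrated MI cutoff at ``pb``.
    """

    def __init__(self, hubs=(), pb: float = 1e-7, dpi_tolerance: float = 0.0,
                 n_boot: int = 100, pc: float = 1e-2, null_pairs: int = 100_000,
                 metacell_gamma: int | None = None, metacell_n_pc: int = 10,
                 alpha: float = 0.05, min_points: int = 8,
                 random_state: int = 0):
        self.hubs = hubs
        self.pb = pb
        self.dpi_tolerance = dpi_tolerance
        self.n_boot = n_boot
        self.pc = pc
        self.null_pairs = null_pairs
        self.metacell_gamma = metacell_gamma
        self.metacell_n_pc = metacell_n_pc
        self.alpha = alpha
        self.min_points = min_points
        self.random_state = random_state

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            hubs=list(self.hubs), pb=self.pb, dpi_tolerance=self.dpi_tolerance,
            n_boot=self.n_boot, pc=self.pc, seed=self.random_state,
            null_pairs=self.null_pairs,
            mi_config=AdaptiveMIConfig(self.alpha, self.min_points),
        )

    def fit(self, X, y=None, feature_names=None):
        """Infer the consensus network.

        Parameters
        ----------
        X : cells x genes array (normalized expression), pandas DataFrame
            (columns = gene names) or :class:`~miner.expression.ExpressionMatrix`.
        feature_names : gene names for a bare array.
        """
        from .expression import ExpressionMatrix

        if isinstance(X, ExpressionMatrix):
            feature_names = X.gene_ids
            mat = X.dense().T
        elif isinstance(X, pd.DataFrame):
            feature_names = X.columns.to_numpy()
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if feature_names is None:
                feature_names = np.array([f"g{i}" for i in range(mat.shape[1])])
        feature_names = np.asarray(feature_names).astype(str)
        cfg = self._config()

        if self.metacell_gamma is not None:
            mc_cfg = MetaCellConfig(self.metacell_gamma, self.metacell_n_pc)
            mat, _ = metacell_aggregate(mat, mc_cfg, seed=self.random_state)

        name_to_idx = {n: i for i, n in enumerate(feature_names)}
        hub_idx = []
        missing = []
        for h in cfg.hubs:
            (hub_idx if h in name_to_idx else missing).append(
                name_to_idx.get(h, h))
        if missing:
            warnings.warn(f"hubs not in the matrix, dropped: {missing}")
        if not hub_idx:
            raise ValueError("no hub gene found in the expression matrix")
        hub_idx = np.asarray(sorted(hub_idx), dtype=np.int64)

        G = mat.T  # genes x samples
        ranks = _rank_uniform(G)
        self.mi_threshold_ = calibrate_mi_null(G, cfg, ranks=ranks)
        raw = bootstrap_consensus(G, hub_idx, self.mi_threshold_, cfg)
        self.network_ = annotate_network(raw, G, feature_names,
                                         set(int(h) for h in hub_idx))
        self.regulons_ = to_regulons(self.network_)
        self.feature_names_in_ = feature_names
        self.n_features_in_ = len(feature_names)
        return self

    def fit_transform_regulons(self, X, **kw):
        return self.fit(X, **kw).regulons_
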