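"""Cell clustering on the mutual-information distance matrix.

Two modes, auto-dispatched on dataset size:

* **MDS mode** (default at <= 5,000 cells): classical multidimensional
  scaling of the MI distance to ``d`` dimensions (19 by default), followed by
  consensus k-means (10 runs aggregated through a co-association matrix).

* **Graph-embedding (GE) mode** (above 5,000 cells): a k1-nearest-neighbor
  similarity graph, node2vec embedding into ``d`` dimensions (20 by
  default), an exact k2-nearest-neighbor graph on the embedding (ball tree),
  and Louvain community detection.

Both are exposed through the scikit-learn style :class:`MICAClustering`
estimator; the module-level functions are the individual pipeline stages.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from ._node2vec import node2vec_embedding
from .mi import MIDistanceMatrix, pairwise_distance

MDS_CELL_CEILING = 5000  # auto mode: <= this many cells -> MDS, else GE


def auto_mode(n_cells: int) -> str:
    """Mode dispatch: MDS for datasets of up to 5,000 cells, GE above."""
    return "mds" if n_cells <= MDS_CELL_CEILING else "ge"


@dataclass
class GraphEmbeddingConfig:
    """Hyperparameters of the graph-embedding clustering mode."""

    k1: int = 80
    d: int = 20
    k2: int = 20
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    p: float = 1.0
    q: float = 1.0
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k2 < 1 or self.k1 <= self.k2:
            raise ValueError("need k1 > k2 >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class ClusterLabels:
    """Integer cluster labels 1..k for an ordered set of cells."""

    labels: np.ndarray
    mode: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = _relabel_consecutive(np.asarray(self.labels))

    @property
    def k(self) -> int:
        return int(self.labels.max())


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary label values onto 1..k preserving first-appearance order."""
    out = np.empty(labels.size, dtype=np.int64)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(lab, len(mapping) + 1)
    return out


def _as_distance_array(dist) -> np.ndarray:
    D = dist.D if isinstance(dist, MIDistanceMatrix) else np.asarray(dist, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return D


def mds_embed(dist, d: int = 19) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix to ``d`` coordinates.

    Eigenvectors of the double-centered squared-distance matrix, scaled by
    the square root of their (positive) eigenvalues; dimensions beyond the
    number of positive eigenvalues are zero-padded.
    """
    D = _as_distance_array(dist)
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:d]
    coords = np.zeros((n, d))
    for out_i, idx in enumerate(order):
        if eigval[idx] > 1e-12:
            v = eigvec[:, idx]
            # deterministic sign: largest-magnitude entry positive
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, out_i] = v * np.sqrt(eigval[idx])
    return coords


def consensus_kmeans(embedding: np.ndarray, k: int, n_runs: int = 10,
                     seed: int = 0) -> ClusterLabels:
    """Aggregate ``n_runs`` seeded k-means runs through a co-association matrix.

    The co-association entry (i, j) is the fraction of runs in which cells i
    and j share a cluster; the final partition is average-linkage
    hierarchical clustering of (1 - co-association), cut at ``k``.
    """
    E = np.asarray(embedding, dtype=float)
    n = E.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} cells")
    coassoc = np.zeros((n, n))
    for run in range(1, n_runs + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                    random_state=seed + run)
        lab = km.fit_predict(E)
        coassoc += (lab[:, None] == lab[None, :])
    coassoc /= n_runs
    if n_runs == 1:
        final = lab
    else:
        agg = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                      linkage="average")
        final = agg.fit_predict(1.0 - coassoc)
    return ClusterLabels(final, mode="mds",
                         params={"k": k, "n_runs": n_runs, "seed": seed})


def knn_graph_from_similarity(dist, k1: int) -> ig.Graph:
    """k1-nearest-neighbor graph on similarity = 1 - D, union-symmetrized, unweighted."""
    D = _as_distance_array(dist)
    n = D.shape[0]
    if k1 >= n:
        raise ValueError(f"k1={k1} must be below the cell count {n}")
    edges = set()
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:k1]
        for j in neighbors:
            edges.add((min(i, j), max(i, j)))
    return ig.Graph(n=n, edges=sorted(edges), directed=False)


def _graph_to_csr(graph: ig.Graph):
    n = graph.vcount()
    adj = [[] for _ in range(n)]
    for e in graph.es:
        a, b = e.tuple
        adj[a].append(b)
        adj[b].append(a)
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices = []
    for i in range(n):
        neighbors = sorted(adj[i])
        indices.extend(neighbors)
        indptr[i + 1] = indptr[i] + len(neighbors)
    return indptr, np.asarray(indices, dtype=np.int64)


def node2vec_embed(graph: ig.Graph, cfg: GraphEmbeddingConfig,
                   dist: np.ndarray | None = None) -> np.ndarray:
    """Node2vec embedding of a cell graph; isolated cells are first attached
    to their nearest cell by MI distance (requires ``dist``)."""
    graph = graph.copy()
    isolated = [v.index for v in graph.vs if graph.degree(v.index) == 0]
    if isolated:
        if dist is None:
            raise ValueError("isolated nodes present but no distance matrix given")
        warnings.warn(f"attaching {len(isolated)} isolated cells to nearest neighbor")
        for i in isolated:
            row = dist[i].copy()
            row[i] = np.inf
            graph.add_edge(i, int(np.argmin(row)))
    indptr, indices = _graph_to_csr(graph)
    return node2vec_embedding(indptr, indices, dim=cfg.d,
                              walks_per_node=cfg.walks_per_node,
                              walk_length=cfg.walk_length, window=cfg.window,
                              p=cfg.p, q=cfg.q, seed=cfg.seed)


def _louvain(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    ig.set_random_number_generator(random.Random(seed))
    try:
        part = graph.community_multilevel(resolution=resolution)
    finally:
        ig.set_random_number_generator(random)
    return np.asarray(part.membership)


def exact_knn_graph(embedding: np.ndarray, k2: int) -> ig.Graph:
    """Exact k2-nearest-neighbor graph in embedding space (ball tree)."""
    E = np.asarray(embedding, dtype=float)
    if k2 >= E.shape[0]:
        raise ValueError("k2 must be below the cell count")
    nn = NearestNeighbors(n_neighbors=k2 + 1, algorithm="ball_tree").fit(E)
    _, idx = nn.kneighbors(E)
    edges = set()
    for i in range(E.shape[0]):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    return ig.Graph(n=E.shape[0], edges=sorted(edges), directed=False)


def louvain_on_exact_knn(embedding: np.ndarray, k2: int = 20,
                         resolution: float = 1.0, seed: int = 0) -> ClusterLabels:
    """Louvain community detection on the exact kNN graph of an embedding."""
    graph = exact_knn_graph(embedding, k2)
    membership = _louvain(graph, resolution, seed)
    return ClusterLabels(membership, mode="ge",
                         params={"k2": k2, "resolution": resolution, "seed": seed})


def sweep_resolution(graph_or_embedding, k_target: int,
                     grid=None, truth=None, k2: int = 20,
                     seed: int = 0) -> ClusterLabels:
    """Sweep the Louvain resolution and return the solution with ``k_target``
    clusters.

    Ties (several resolutions hitting ``k_target``) are broken by highest ARI
    against ``truth`` when given, else by lowest resolution.
    """
    if k_target < 2:
        raise ValueError("k_target must be >= 2")
    if grid is None:
        grid = np.round(np.arange(0.1, 4.0 + 1e-9, 0.1), 10)
    if isinstance(graph_or_embedding, ig.Graph):
        graph = graph_or_embedding
    else:
        graph = exact_knn_graph(np.asarray(graph_or_embedding, float), k2)
    achieved = {}
    candidates = []
    for res in grid:
        membership = _louvain(graph, float(res), seed)
        k = len(np.unique(membership))
        achieved[float(res)] = k
        if k == k_target:
            candidates.append((float(res), membership))
    if not candidates:
        raise ValueError(
            f"no resolution in the grid yields {k_target} clusters; "
            f"achieved counts: {achieved}"
        )
    if truth is not None:
        truth = np.asarray(truth)
        best = max(candidates, key=lambda c: adjusted_rand_score(truth, c[1]))
    else:
        best = candidates[0]
    return ClusterLabels(best[1], mode="ge",
                         params={"resolution": best[0], "k_target": k_target,
                                 "seed": seed})


class MICAClustering(ClusterMixin, BaseEstimator):
    """Mutual-information-based cell clustering (MI distance + MDS/GE modes).

    Parameters
    ----------
    n_clusters : int
        Number of clusters for MDS-mode k-means. Ignored in GE mode unless
        ``sweep_to_n_clusters`` is set.
    mode : {"auto", "mds", "ge"}
        ``"auto"`` picks MDS at <= 5,000 cells and GE above.
    bins : "auto" or int
        Histogram bin count for the MI distance (cube-root rule by default).
    mds_dims : int
        MDS embedding dimensionality (MDS mode).
    n_kmeans : int
        Number of consensus k-means runs (MDS mode).
    k1, embed_dim, k2, resolution : GE-mode graph/embedding parameters.
    sweep_to_n_clusters : bool
        In GE mode, sweep the Louvain resolution over 0.1..4 (step 0.1) until
        ``n_clusters`` communities are found.
    random_state : int
        Seed for every stochastic stage.

    Attributes
    ----------
    labels_ : integer cluster labels (1..k) per cell.
    distance_ : the :class:`~miner.mi.MIDistanceMatrix`.
    embedding_ : cells x d coordinates used for clustering.
    mode_ : the mode actually run ("mds" or "ge").
    """

    def __init__(self, n_clusters: int = 2, mode: str = "auto", bins="auto",
                 mds_dims: int = 19, n_kmeans: int = 10, k1: int = 80,
                 embed_dim: int = 20, k2: int = 20, resolution: float = 1.0,
                 sweep_to_n_clusters: bool = False, block_size: int | None = None,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.mode = mode
        self.bins = bins
        self.mds_dims = mds_dims
        self.n_kmeans = n_kmeans
        self.k1 = k1
        self.embed_dim = embed_dim
        self.k2 = k2
        self.resolution = resolution
        self.sweep_to_n_clusters = sweep_to_n_clusters
        self.block_size = block_size
        self.random_state = random_state

    def fit(self, X, y=None):
        """Cluster cells.

        Parameters
        ----------
        X : cells x genes array of normalized (log-scale) expression, or a
            precomputed :class:`~miner.mi.MIDistanceMatrix`.
        """
        if isinstance(X, MIDistanceMatrix):
            dist = X
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[0] < 3:
                raise ValueError("need at least 3 cells")
            if X.shape[0] < 500:
                warnings.warn("fewer than 500 cells; MI distances may be noisy")
            dist = pairwise_distance(X, b=self.bins, block_size=self.block_size)
        n = dist.n_cells
        if self.mode == "auto":
            mode = auto_mode(n)
        elif self.mode in ("mds", "ge"):
            mode = self.mode
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.distance_ = dist
        self.mode_ = mode
        if mode == "mds":
            self.embedding_ = mds_embed(dist, d=self.mds_dims)
            result = consensus_kmeans(self.embedding_, k=self.n_clusters,
                                      n_runs=self.n_kmeans,
                                      seed=self.random_state)
        else:
            cfg = GraphEmbeddingConfig(k1=min(self.k1, n - 1), d=self.embed_dim,
                                       k2=self.k2, resolution=self.resolution,
                                       seed=self.random_state)
            graph = knn_graph_from_similarity(dist, cfg.k1)
            self.embedding_ = node2vec_embed(graph, cfg, dist=dist.D)
            if self.sweep_to_n_clusters:
                result = sweep_resolution(self.embedding_, self.n_clusters,
                                          k2=self.k2, seed=self.random_state)
            else:
                result = louvain_on_exact_knn(self.embedding_, k2=self.k2,
                                              resolution=self.resolution,
                                              seed=self.random_state)
        self.labels_ = result.labels
        self.n_clusters_ = result.k
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def mica(m, mode: str = "auto", n_clusters: int = 2, **params) -> ClusterLabels:
    """Full pipeline on an :class:`~miner.expression.ExpressionMatrix`:
    MI distance -> embedding -> clustering."""
    from .expression import ExpressionMatrix

    X = m.dense().T if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    est = MICAClustering(n_clusters=n_clusters, mode=mode, **params).fit(X)
    return ClusterLabels(est.labels_, mode=est.mode_,
                         params={"n_clusters": n_clusters,
                                 "seed": est.random_state})
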