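"""Mutual information kernels.

Two estimators live here:

* a fixed-grid histogram estimator for cell-cell distances
  (``mi_entropy_distance`` / ``pairwise_distance``): expression vectors are
  discretized into ``b`` equal-width bins (``b = round(n_genes ** (1/3))`` by
  default) and I(x;y), H(x,y) are computed from the joint histogram, both in
  bits; the normalized distance is ``D = 1 - I/H``.

* an adaptive-partitioning estimator for gene-gene dependency
  (``adaptive_mi``): both vectors are rank-transformed to uniform marginals
  and the unit square is recursively quadrisected, splitting a cell only
  where its four quadrant counts deviate significantly from uniform
  (chi-square goodness-of-fit). This adapts resolution to where the joint
  density actually varies, which a fixed grid cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, prange
from scipy.stats import chi2, rankdata

__all__ = [
    "default_bin_size",
    "discretize",
    "mi_entropy_distance",
    "pairwise_distance",
    "adaptive_mi",
    "AdaptiveMIConfig",
    "MIDistanceMatrix",
    "block_plan",
]


def default_bin_size(n_genes: int) -> int:
    """Cube-root rule for the histogram bin count, floored at 2."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return max(2, int(round(n_genes ** (1.0 / 3.0))))


def discretize(x, b: int) -> np.ndarray:
    """Equal-width binning of ``x`` into bins ``0..b-1`` over [min(x), max(x)].

    The maximum maps into the last bin; a constant vector maps to bin 0.
    """
    if b < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.int64)
    idx = np.floor((x - lo) / (hi - lo) * b).astype(np.int64)
    return np.minimum(idx, b - 1)


@njit(cache=True)
def _hist_mi_entropy(xb, yb, b):
    n = xb.size
    joint = np.zeros((b, b), dtype=np.float64)
    for g in range(n):
        joint[xb[g], yb[g]] += 1.0
    px = np.zeros(b, dtype=np.float64)
    py = np.zeros(b, dtype=np.float64)
    for i in range(b):
        for j in range(b):
            px[i] += joint[i, j]
            py[j] += joint[i, j]
    inv = 1.0 / n
    mi = 0.0
    ent = 0.0
    for i in range(b):
        for j in range(b):
            c = joint[i, j]
            if c > 0.0:
                p = c * inv
                ent -= p * np.log2(p)
                mi += p * np.log2(p / (px[i] * inv * py[j] * inv))
    return mi, ent


def mi_entropy_distance(x, y, b: int) -> tuple[float, float, float]:
    """Histogram MI, joint entropy and normalized distance for one vector pair.

    Returns ``(I, H, D)`` with I, H in bits and ``D = 1 - I/H``; when both
    vectors are constant (H = 0) the pair is treated as identical, ``D = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xb = discretize(x, b)
    yb = discretize(y, b)
    mi, ent = _hist_mi_entropy(xb, yb, b)
    d = 0.0 if ent == 0.0 else 1.0 - mi / ent
    return float(mi), float(ent), float(d)


@dataclass
class MIDistanceMatrix:
    """Pairwise normalized MI distance over cells.

    ``D`` is symmetric with zero diagonal and entries in [0, 1];
    ``I`` and ``H`` hold the matching mutual information and joint entropy.
    """

    cells: np.ndarray
    D: np.ndarray
    I: np.ndarray
    H: np.ndarray
    b_used: int

    @property
    def n_cells(self) -> int:
        return self.D.shape[0]


def block_plan(n_cells: int, block_size: int | None) -> list[tuple[int, int]]:
    """Upper-triangle block index pairs for partitioned pairwise computation."""
    if block_size is None or block_size >= n_cells:
        return [(0, 0)]
    n_blocks = int(np.ceil(n_cells / block_size))
    return [(i, j) for i in range(n_blocks) for j in range(i, n_blocks)]


@njit(cache=True, parallel=True)
def _pairwise_kernel(binned, b, pairs, mi_out, ent_out):
    for p in prange(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        mi, ent = _hist_mi_entropy(binned[i], binned[j], b)
        mi_out[p] = mi
        ent_out[p] = ent


def pairwise_distance(m, b="auto", block_size: int | None = None) -> MIDistanceMatrix:
    """All-pairs normalized MI distance between cells.

    Parameters
    ----------
    m
        An :class:`~miner.expression.ExpressionMatrix` (normalized) or a
        cells x genes array.
    b
        Bin count, or ``"auto"`` for the cube-root rule on the gene count.
    block_size
        Cells per partition block. Purely a work-scheduling contract: each
        cell vector is discretized once globally, so the result is identical
        for every block size.
    """
    from .expression import ExpressionMatrix

    if isinstance(m, ExpressionMatrix):
        X = m.dense().T  # cells x genes
        barcodes = m.cell_barcodes
    else:
        X = np.asarray(m, dtype=float)
        barcodes = np.arange(X.shape[0])
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if b == "auto":
        b = default_bin_size(n_genes)
    b = int(b)

    binned = np.empty((n_cells, n_genes), dtype=np.int64)
    for i in range(n_cells):
        binned[i] = discretize(X[i], b)

    I = np.zeros((n_cells, n_cells))
    H = np.zeros((n_cells, n_cells))
    bs = n_cells if block_size is None else int(block_size)
    for bi, bj in block_plan(n_cells, bs):
        i0, i1 = bi * bs, min((bi + 1) * bs, n_cells)
        j0, j1 = bj * bs, min((bj + 1) * bs, n_cells)
        pairs = [(i, j) for i in range(i0, i1) for j in range(max(j0, i + 1), j1)]
        if not pairs:
            continue
        pairs = np.asarray(pairs, dtype=np.int64)
        mi_out = np.empty(pairs.shape[0])
        ent_out = np.empty(pairs.shape[0])
        _pairwise_kernel(binned, b, pairs, mi_out, ent_out)
        I[pairs[:, 0], pairs[:, 1]] = mi_out
        H[pairs[:, 0], pairs[:, 1]] = ent_out
    I = I + I.T
    H = H + H.T
    for i in range(n_cells):
        mi, ent = _hist_mi_entropy(binned[i], binned[i], b)
        I[i, i] = mi
        H[i, i] = ent
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(H > 0, 1.0 - I / H, 0.0)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    return MIDistanceMatrix(cells=np.asarray(barcodes), D=D, I=I, H=H, b_used=b)


@dataclass
class AdaptiveMIConfig:
    """Settings for the adaptive-partitioning MI estimator.

    ``alpha`` is the significance level of the quadrant-uniformity
    chi-square test; a cell is split only when the test rejects and the cell
    holds at least ``min_points`` points.
    """

    alpha: float = 0.05
    min_points: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_points < 4:
            raise ValueError("min_points must be >= 4")


@njit(cache=True)
def _adaptive_mi_ranks(rx, ry, chi2_crit, min_points):
    n = rx.size
    min_width = 1.0 / n
    # explicit stack: (start, end, xlo, xhi, ylo, yhi); depth is O(log n)
    cap = 512
    st_s = np.empty(cap, dtype=np.int64)
    st_e = np.empty(cap, dtype=np.int64)
    st_b = np.empty((cap, 4), dtype=np.float64)
    idx = np.arange(n)
    tmp = np.empty(n, dtype=np.int64)
    top = 0
    st_s[0] = 0
    st_e[0] = n
    st_b[0, 0] = 0.0
    st_b[0, 1] = 1.0
    st_b[0, 2] = 0.0
    st_b[0, 3] = 1.0
    top = 1
    mi = 0.0
    while top > 0:
        top -= 1
        s = st_s[top]
        e = st_e[top]
        xlo = st_b[top, 0]
        xhi = st_b[top, 1]
        ylo = st_b[top, 2]
        yhi = st_b[top, 3]
        cnt = e - s
        if cnt == 0:
            continue
        splittable = (cnt >= min_points and
                      (xhi - xlo >= min_width or yhi - ylo >= min_width))
        if splittable:
            mx = 0.5 * (xlo + xhi)
            my = 0.5 * (ylo + yhi)
            c0 = 0
            c1 = 0
            c2 = 0
            c3 = 0
            for k in range(s, e):
                p = idx[k]
                right = rx[p] > mx
                upper = ry[p] > my
                if right:
                    if upper:
                        c3 += 1
                    else:
                        c1 += 1
                else:
                    if upper:
                        c2 += 1
                    else:
                        c0 += 1
            exp = cnt / 4.0
            stat = ((c0 - exp) ** 2 + (c1 - exp) ** 2 +
                    (c2 - exp) ** 2 + (c3 - exp) ** 2) / exp
            if stat > chi2_crit:
                # stable 4-way partition of idx[s:e] by quadrant
                o0 = s
                o1 = o0 + c0
                o2 = o1 + c1
                o3 = o2 + c2
                for k in range(s, e):
                    tmp[k] = idx[k]
                for k in range(s, e):
                    p = tmp[k]
                    right = rx[p] > mx
                    upper = ry[p] > my
                    if right:
                        if upper:
                            idx[o3] = p
                            o3 += 1
                        else:
                            idx[o1] = p
                            o1 += 1
                    else:
                        if upper:
                            idx[o2] = p
                            o2 += 1
                        else:
                            idx[o0] = p
                            o0 += 1
                quad_counts = (c0, c1, c2, c3)
                starts = (s, s + c0, s + c0 + c1, s + c0 + c1 + c2)
                bounds = ((xlo, mx, ylo, my), (mx, xhi, ylo, my),
                          (xlo, mx, my, yhi), (mx, xhi, my, yhi))
                for q in range(4):
                    if quad_counts[q] > 0:
                        st_s[top] = starts[q]
                        st_e[top] = starts[q] + quad_counts[q]
                        st_b[top, 0] = bounds[q][0]
                        st_b[top, 1] = bounds[q][1]
                        st_b[top, 2] = bounds[q][2]
                        st_b[top, 3] = bounds[q][3]
                        top += 1
                continue
        # leaf: uniform-marginal probability is the cell's rank-space area
        pj = cnt / n
        area = (xhi - xlo) * (yhi - ylo)
        mi += pj * np.log2(pj / area)
    if mi < 0.0:
        mi = 0.0
    return mi


def adaptive_mi(x, y, cfg: AdaptiveMIConfig | None = None) -> float:
    """Adaptive-partitioning mutual information of two vectors, in bits.

    Both vectors are rank-transformed (average ranks for ties) so marginals
    are uniform; the estimate is therefore invariant under strictly monotone
    transforms of either input.
    """
    if cfg is None:
        cfg = AdaptiveMIConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 points for adaptive MI")
    rx = (rankdata(x) - 0.5) / n
    ry = (rankdata(y) - 0.5) / n
    crit = chi2.isf(cfg.alpha, df=3)
    return float(_adaptive_mi_ranks(rx, ry, crit, cfg.min_points))


def _rank_uniform(X: np.ndarray) -> np.ndarray:
    """Row-wise centered rank transform to (0, 1), average ranks for ties.

    The half-offset (r - 0.5)/n keeps the transform symmetric about 0.5, so
    the estimator treats positive and negative dependence identically.
    """
    n = X.shape[1]
    return np.vstack([(rankdata(row) - 0.5) / n for row in X])


@njit(cache=True, parallel=True)
def _adaptive_mi_pairs_kernel(R, pairs, chi2_crit, min_points, out):
    for p in prange(pairs.shape[0]):
        out[p] = _adaptive_mi_ranks(R[pairs[p, 0]], R[pairs[p, 1]],
                                    chi2_crit, min_points)


def adaptive_mi_pairs(X: np.ndarray, pairs: np.ndarray,
                      cfg: AdaptiveMIConfig | None = None,
                      ranks: np.ndarray | None = None) -> np.ndarray:
    """Adaptive MI for many (row_i, row_j) pairs of a genes x samples matrix.

    ``ranks`` may carry a precomputed rank transform of ``X`` to amortize it
    across calls (e.g. bootstrap iterations reuse resampled ranks).
    """
    if cfg is None:
        cfg = AdaptiveMIConfig()
    R = _rank_uniform(np.asarray(X, dtype=float)) if ranks is None else ranks
    pairs = np.asarray(pairs, dtype=np.int64)
    out = np.empty(pairs.shape[0])
    crit = chi2.isf(cfg.alpha, df=3)
    _adaptive_mi_pairs_kernel(R, pairs, crit, cfg.min_points, out)
    return out
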