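"""Node2vec: biased second-order random walks + skip-gram with negative sampling.

Small, seeded, numba-accelerated word2vec core specialised to graph walks
(the vocabulary is the node set, so no subsampling or vocab pruning is
needed). Walk bias follows the usual return/in-out parameters p and q; with
p = q = 1 the walk is a plain first-order random walk.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lcg(state):
    # 64-bit LCG (MMIX constants); returns (new_state, uniform in [0,1))
    state = state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    return state, float(state >> np.uint64(11)) / 9007199254740992.0


@njit(cache=True)
def _is_neighbor(indices, start, end, v):
    lo, hi = start, end
    while lo < hi:
        mid = (lo + hi) // 2
        if indices[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    return lo < end and indices[lo] == v


@njit(cache=True)
def _generate_walks(indptr, indices, walks_per_node, walk_length, p, q, seed):
    n = indptr.size - 1
    walks = np.full((n * walks_per_node, walk_length), -1, dtype=np.int64)
    state = np.uint64(seed * 2654435761 + 1)
    w = 0
    for r in range(walks_per_node):
        for start in range(n):
            walks[w, 0] = start
            prev = -1
            cur = start
            for step in range(1, walk_length):
                deg = indptr[cur + 1] - indptr[cur]
                if deg == 0:
                    break
                if prev < 0 or (p == 1.0 and q == 1.0):
                    state, u = _lcg(state)
                    nxt = indices[indptr[cur] + int(u * deg)]
                else:
                    # weights: 1/p to return, 1 to common neighbor, 1/q outward
                    total = 0.0
                    for k in range(indptr[cur], indptr[cur + 1]):
                        v = indices[k]
                        if v == prev:
                            total += 1.0 / p
                        elif _is_neighbor(indices, indptr[prev], indptr[prev + 1], v):
                            total += 1.0
                        else:
                            total += 1.0 / q
                    state, u = _lcg(state)
                    target = u * total
                    acc = 0.0
                    nxt = indices[indptr[cur + 1] - 1]
                    for k in range(indptr[cur], indptr[cur + 1]):
                        v = indices[k]
                        if v == prev:
                            acc += 1.0 / p
                        elif _is_neighbor(indices, indptr[prev], indptr[prev + 1], v):
                            acc += 1.0
                        else:
                            acc += 1.0 / q
                        if acc >= target:
                            nxt = v
                            break
                walks[w, step] = nxt
                prev = cur
                cur = nxt
            w += 1
    return walks


@njit(cache=True)
def _train_sgns(walks, n_nodes, dim, window, negatives, epochs, lr0, noise_cdf,
                seed):
    state = np.uint64(seed * 1099511628211 + 3)
    # init like word2vec: input vectors uniform in [-0.5/d, 0.5/d], context zero
    W = np.empty((n_nodes, dim))
    C = np.zeros((n_nodes, dim))
    for i in range(n_nodes):
        for k in range(dim):
            state, u = _lcg(state)
            W[i, k] = (u - 0.5) / dim
    n_walks, walk_len = walks.shape
    total_steps = epochs * n_walks
    step_count = 0
    order = np.arange(n_walks)
    for ep in range(epochs):
        # deterministic Fisher-Yates shuffle so SGD does not sweep nodes in
        # generation order every epoch
        for t in range(n_walks - 1, 0, -1):
            state, u = _lcg(state)
            s = int(u * (t + 1))
            tmp_i = order[t]
            order[t] = order[s]
            order[s] = tmp_i
        for oi in range(n_walks):
            wi = order[oi]
            lr = lr0 * (1.0 - step_count / (total_steps + 1.0))
            if lr < lr0 * 0.0001:
                lr = lr0 * 0.0001
            step_count += 1
            for pos in range(walk_len):
                center = walks[wi, pos]
                if center < 0:
                    break
                # dynamic window, as in word2vec
                state, u = _lcg(state)
                b = int(u * window)
                lo = pos - window + b
                hi = pos + window - b
                if lo < 0:
                    lo = 0
                if hi >= walk_len:
                    hi = walk_len - 1
                for cpos in range(lo, hi + 1):
                    ctx = walks[wi, cpos]
                    if cpos == pos or ctx < 0:
                        continue
                    # one positive + `negatives` sampled negatives
                    for s in range(negatives + 1):
                        if s == 0:
                            tgt = ctx
                            label = 1.0
                        else:
                            state, u = _lcg(state)
                            tgt = np.searchsorted(noise_cdf, u)
                            if tgt == center:
                                continue
                            label = 0.0
                        dot = 0.0
                        for k in range(dim):
                            dot += W[center, k] * C[tgt, k]
                        if dot > 8.0:
                            g = (label - 1.0) * lr
                        elif dot < -8.0:
                            g = label * lr
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-dot))) * lr
                        for k in range(dim):
                            tmp = g * C[tgt, k]
                            C[tgt, k] += g * W[center, k]
                            W[center, k] += tmp
    return W


def node2vec_embedding(indptr: np.ndarray, indices: np.ndarray, dim: int = 20,
                       walks_per_node: int = 10, walk_length: int = 80,
                       window: int = 10, p: float = 1.0, q: float = 1.0,
                       negatives: int = 5, epochs: int = 1,
                       learning_rate: float = 0.025,
                       seed: int = 0) -> np.ndarray:
    """Embed the nodes of a CSR adjacency (indptr/indices) into ``dim`` coords."""
    n = indptr.size - 1
    walks = _generate_walks(indptr.astype(np.int64), indices.astype(np.int64),
                            walks_per_node, walk_length, float(p), float(q),
                            int(seed) % (2**31 - 1) + 1)
    # unigram^0.75 noise distribution over node frequency in the walks
    freq = np.bincount(walks[walks >= 0].ravel(), minlength=n).astype(float)
    freq = np.maximum(freq, 1.0) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())
    noise_cdf[-1] = 1.0
    return _train_sgns(walks, n, dim, window, negatives, epochs,
                       learning_rate, noise_cdf,
                       int(seed) % (2**31 - 1) + 7)
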