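"""Numba kernels: second-order biased random walks and skip-gram training.

Both kernels are single-threaded and draw all randomness from numba's
per-thread NumPy RNG seeded at kernel entry, so a fixed seed gives bitwise
reproducible walks and vectors. The skip-gram trainer follows the classic
word2vec SGD scheme: negative sampling against a unigram^0.75 noise
distribution, a per-position window radius drawn uniformly from [1, window],
and a learning rate decaying linearly over all scheduled positions.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=False, inline="always")
def _has_edge(indptr, nbrs, a, b):
    lo = indptr[a]
    hi = indptr[a + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = nbrs[mid]
        if v == b:
            return True
        if v < b:
            lo = mid + 1
        else:
            hi = mid
    return False


@nb.njit(cache=False)
def walk_kernel(indptr, nbrs, weights, node_bias, starts, walk_length,
                p_ret, q_io, seed):
    """Generate one walk per start node; -1 pads walks cut short.

    Transition weight from ``cur`` to neighbour ``x`` given previous node
    ``prev``: ``w(cur,x) / p`` if x == prev, ``w(cur,x)`` if x neighbours
    prev, else ``w(cur,x) / q`` (the node2vec second-order bias, modulated
    by edge confidence), finally multiplied by ``node_bias[x]`` (the
    score-aware attraction toward perturbed nodes; all ones when the walk
    is topology-only).
    """
    np.random.seed(seed)
    n_walks = starts.shape[0]
    out = np.full((n_walks, walk_length), -1, dtype=np.int32)
    cum = np.empty(indptr.shape[0], dtype=np.float64)  # scratch, max degree
    for w in range(n_walks):
        cur = starts[w]
        out[w, 0] = cur
        prev = -1
        for step in range(1, walk_length):
            lo = indptr[cur]
            hi = indptr[cur + 1]
            m = hi - lo
            if m == 0:
                break
            total = 0.0
            for i in range(m):
                x = nbrs[lo + i]
                wgt = weights[lo + i] * node_bias[x]
                if prev >= 0:
                    if x == prev:
                        wgt /= p_ret
                    elif not _has_edge(indptr, nbrs, prev, x):
                        wgt /= q_io
                total += wgt
                cum[i] = total
            r = np.random.random() * total
            j = 0
            while j < m - 1 and cum[j] <= r:
                j += 1
            nxt = nbrs[lo + j]
            out[w, step] = nxt
            prev = cur
            cur = nxt
    return out


@nb.njit(cache=False, fastmath=True)
def sgns_kernel(walks, walk_lens, syn0, syn1, window, negative,
                alpha0, alpha_min, epochs, noise_cum, keep_prob, seed):
    """Train skip-gram with negative sampling in place on syn0/syn1.

    ``keep_prob`` implements word2vec frequency subsampling: each token
    occurrence survives with its node's keep probability, and windows run
    over the compacted sequence. Without it, nodes that dominate the walk
    corpus (hubs, and strongly perturbed nodes under the score-biased
    walk) saturate the objective and blur the geometry.
    """
    np.random.seed(seed)
    d = syn0.shape[1]
    n_walks = walks.shape[0]
    max_len = walks.shape[1]
    total_positions = 0
    for i in range(n_walks):
        total_positions += walk_lens[i]
    total_positions *= epochs
    processed = 0
    neu1e = np.empty(d, dtype=np.float64)
    kept = np.empty(max_len, dtype=np.int32)
    for _ep in range(epochs):
        for wi in range(n_walks):
            raw_len = walk_lens[wi]
            length = 0
            for pos in range(raw_len):
                tok = walks[wi, pos]
                if np.random.random() < keep_prob[tok]:
                    kept[length] = tok
                    length += 1
            processed += raw_len
            frac = processed / total_positions
            alpha = alpha0 - (alpha0 - alpha_min) * frac
            for pos in range(length):
                center = kept[pos]
                radius = 1 + np.int64(np.random.random() * window)
                lo = pos - radius
                if lo < 0:
                    lo = 0
                hi = pos + radius + 1
                if hi > length:
                    hi = length
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = kept[cpos]
                    for k in range(d):
                        neu1e[k] = 0.0
                    for ns in range(negative + 1):
                        if ns == 0:
                            target = center
                            label = 1.0
                        else:
                            r = np.random.random()
                            target = np.searchsorted(noise_cum, r)
                            if target >= noise_cum.shape[0]:
                                target = noise_cum.shape[0] - 1
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for k in range(d):
                            f += syn0[ctx, k] * syn1[target, k]
                        if f > 6.0:
                            g = (label - 1.0) * alpha
                        elif f < -6.0:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        for k in range(d):
                            neu1e[k] += g * syn1[target, k]
                        for k in range(d):
                            syn1[target, k] += g * syn0[ctx, k]
                    for k in range(d):
                        syn0[ctx, k] += neu1e[k]
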