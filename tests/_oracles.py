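"""Independent reference implementations used to check the fast code paths.

These are deliberately naive (quadratic loops, explicit SSE sums) and share
no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def sse(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0


def naive_greedy_cuts(y, complexity: float, min_leaf: int) -> list[int]:
    """Transparent reimplementation of the greedy cp-rule tree.

    Recursively splits [lo, hi): tries every cut leaving >= min_leaf on both
    sides, accepts the leftmost best cut if it lowers node SSE by at least
    complexity * SSE(root) (and strictly lowers it at all).
    """
    y = np.asarray(y, dtype=float)
    threshold = complexity * sse(y)
    cuts: list[int] = []

    def grow(lo, hi):
        if hi - lo < 2 * min_leaf:
            return
        best_gain, best_i = -np.inf, None
        node_sse = sse(y[lo:hi])
        for i in range(lo + min_leaf, hi - min_leaf + 1):
            g = node_sse - sse(y[lo:i]) - sse(y[i:hi])
            if g > best_gain + 1e-12:  # strict: ties keep the leftmost cut
                best_gain, best_i = g, i
        if best_i is None or best_gain < threshold or best_gain <= 0:
            return
        cuts.append(best_i)
        grow(lo, best_i)
        grow(best_i, hi)

    grow(0, len(y))
    return sorted(cuts)


def optimal_cuts_dp(y, n_pieces: int, min_leaf: int) -> list[int] | None:
    """Minimal-SSE partition of y into exactly n_pieces, each >= min_leaf.

    Exhaustive dynamic programme, O(n^2 * k); returns sorted interior cut
    indices, or None when infeasible.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    seg_sse = np.full((n + 1, n + 1), np.inf)
    for a in range(n):
        for b in range(a + min_leaf, n + 1):
            seg_sse[a][b] = sse(y[a:b])
    INF = np.inf
    cost = np.full((n_pieces + 1, n + 1), INF)
    back = np.zeros((n_pieces + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for k in range(1, n_pieces + 1):
        for b in range(k * min_leaf, n + 1):
            for a in range((k - 1) * min_leaf, b - min_leaf + 1):
                c = cost[k - 1][a] + seg_sse[a][b]
                if c < cost[k][b] - 1e-12:
                    cost[k][b] = c
                    back[k][b] = a
    if not np.isfinite(cost[n_pieces][n]):
        return None
    cuts = []
    b = n
    for k in range(n_pieces, 1, -1):
        b = back[k][b]
        cuts.append(b)
    return sorted(cuts)


def normal_upper_tail(z: float) -> float:
    """1 - Phi(z) via the complementary error function, no scipy.stats."""
    import math

    return 0.5 * math.erfc(z / math.sqrt(2.0))
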