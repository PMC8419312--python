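"""Numba kernels for the hot loops of the null-model pipeline.

A full run touches ~200k rewired null graphs (subjects x densities x
nulls), so the double-edge-swap rewiring and the all-pairs BFS are jitted.
All randomness is pre-drawn with numpy Generators outside the kernels, so
results are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rewire_kernel(adj, u, v, pick1, pick2, orient):  # pragma: no cover - jitted
    """Maslov–Sneppen double edge swaps, in place.

    adj is the dense boolean adjacency; (u, v) the edge list, rewritten as
    swaps succeed. Each attempt t proposes replacing edges (a,b),(c,d) by
    (a,d),(c,b) and is skipped if it would create a self-loop or a
    duplicate edge. Returns the number of successful swaps.
    """
    n_ok = 0
    for t in range(pick1.shape[0]):
        e1 = pick1[t]
        e2 = pick2[t]
        if e1 == e2:
            continue
        a = u[e1]
        b = v[e1]
        c = u[e2]
        d = v[e2]
        if orient[t] == 1:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        u[e1] = a
        v[e1] = d
        u[e2] = c
        v[e2] = b
        n_ok += 1
    return n_ok


@njit(cache=True)
def cp_lp_kernel(adj):  # pragma: no cover - jitted
    """Mean local clustering and characteristic path length of one graph.

    Clustering of a node with degree < 2 is 0 and still enters the mean.
    Path length is the mean BFS distance over all ordered reachable pairs;
    the third return value is the fraction of ordered pairs that are
    unreachable (0 for a connected graph).
    """
    n = adj.shape[0]
    deg = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                deg[i] += 1
    indptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + deg[i]
    nbr = np.empty(indptr[n], np.int64)
    pos = indptr[:-1].copy()
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                nbr[pos[i]] = j
                pos[i] += 1

    csum = 0.0
    for i in range(n):
        k = deg[i]
        if k >= 2:
            tri = 0
            for a in range(indptr[i], indptr[i + 1]):
                x = nbr[a]
                for b in range(a + 1, indptr[i + 1]):
                    if adj[x, nbr[b]]:
                        tri += 1
            csum += 2.0 * tri / (k * (k - 1.0))
    cp = csum / n

    total = 0.0
    reach = 0
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            x = queue[head]
            head += 1
            dx = dist[x]
            for a in range(indptr[x], indptr[x + 1]):
                y = nbr[a]
                if dist[y] < 0:
                    dist[y] = dx + 1
                    queue[tail] = y
                    tail += 1
        for y in range(n):
            if y != s and dist[y] > 0:
                total += dist[y]
                reach += 1
    if reach > 0:
        lp = total / reach
    else:
        lp = np.nan
    frac_unreachable = 1.0 - reach / (n * (n - 1.0))
    return cp, lp, frac_unreachable
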