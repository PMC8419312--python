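"""Independent brute-force graph-metric oracles for the test suite.

Deliberately naive: triangle counting by triple loops, Floyd-Warshall
distances, betweenness by explicit enumeration of every shortest path.
These never touch the package's implementations.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def bf_clustering(adj: np.ndarray) -> float:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nbrs[x], nbrs[y]]:
                    links += 1
        total += 2.0 * links / (k * (k - 1))
    return total / n


def bf_distances(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_path_length(adj: np.ndarray) -> tuple[float, float]:
    """(mean distance over reachable ordered pairs, unreachable fraction)."""
    d = bf_distances(adj)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and d[i, j] < INF]
    n_pairs = n * (n - 1)
    if not vals:
        return float("nan"), 1.0
    return float(np.mean(vals)), 1.0 - len(vals) / n_pairs


def bf_degree_centrality(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj, dtype=bool)
    return a.sum(axis=0) / (a.shape[0] - 1)


def _all_shortest_paths(adj: np.ndarray, d: np.ndarray, s: int, t: int):
    """Every shortest s-t path, by recursive descent along the distances."""
    n = adj.shape[0]
    if d[s, t] == INF:
        return []
    if s == t:
        return [[s]]
    paths = []
    for u in range(n):
        if adj[s, u] and d[u, t] == d[s, t] - 1:
            for rest in _all_shortest_paths(adj, d, u, t):
                paths.append([s] + rest)
    return paths


def bf_betweenness(adj: np.ndarray, normalized: bool = True) -> np.ndarray:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = bf_distances(a)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(a, d, s, t)
            if not paths:
                continue
            for v in range(n):
                if v == s or v == t:
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, k=1)
    return a | a.T
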