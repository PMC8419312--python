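"""Topological metrics: clustering, path length, small-worldness, centrality.

Small-worldness follows the standard normalized form

    gamma = Cp / <Cp_rand>,  lambda = Lp / <Lp_rand>,  sigma = gamma / lambda,

where the null averages are over an ensemble of degree-preserving
(Maslov–Sneppen) rewirings of the observed graph. sigma > 1 is the
small-world regime: more clustered than random at comparable path length.

Conventions: local clustering of a node with degree < 2 is 0 and enters
the mean; path length averages over reachable pairs only, with the
unreachable fraction reported alongside.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._kernels import cp_lp_kernel, rewire_kernel
from .datatypes import BinaryGraph, SmallWorldResult

CENTRALITY_KINDS = ("degree", "betweenness")


def _cp_lp(adj: np.ndarray) -> tuple[float, float, float]:
    cp, lp, frac = cp_lp_kernel(np.ascontiguousarray(adj, dtype=bool))
    return float(cp), float(lp), float(frac)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean local clustering coefficient (degree-<2 nodes contribute 0)."""
    if g.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    cp, _, _ = _cp_lp(g.adjacency)
    return cp


def characteristic_path_length(g: BinaryGraph) -> tuple[float, float]:
    """Mean shortest-path length over reachable ordered pairs.

    Returns (lp, frac_unreachable). Raises if the graph has no edges,
    since no pair is then reachable.
    """
    if g.n_edges == 0:
        raise ValueError("graph has no edges: no reachable pairs")
    _, lp, frac = _cp_lp(g.adjacency)
    return lp, frac


def rewire_null(
    g: BinaryGraph,
    n_swap_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> BinaryGraph:
    """Degree-preserving randomization by repeated double edge swaps.

    Attempts ``n_swap_per_edge * m`` swaps; illegal proposals (self-loop
    or duplicate edge) are skipped. The degree sequence is preserved
    exactly. On a complete graph no proposal is legal, so the output
    equals the input.
    """
    if g.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = g.edge_list()
    m = edges.shape[0]
    adj = g.adjacency.copy()
    u = np.ascontiguousarray(edges[:, 0], dtype=np.int64)
    v = np.ascontiguousarray(edges[:, 1], dtype=np.int64)
    n_try = int(n_swap_per_edge) * m
    rewire_kernel(
        adj,
        u,
        v,
        rng.integers(0, m, n_try),
        rng.integers(0, m, n_try),
        rng.integers(0, 2, n_try),
    )
    return BinaryGraph(adjacency=adj, density=g.density, roi_labels=list(g.roi_labels))


def _null_ensemble_means(
    adj: np.ndarray,
    edges: np.ndarray,
    n_nulls: int,
    n_swap_per_edge: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean Cp and Lp over rewired nulls, computed on raw arrays."""
    m = edges.shape[0]
    n_try = n_swap_per_edge * m
    cps = np.empty(n_nulls)
    lps = np.empty(n_nulls)
    for i in range(n_nulls):
        a = adj.copy()
        u = np.ascontiguousarray(edges[:, 0], dtype=np.int64)
        v = np.ascontiguousarray(edges[:, 1], dtype=np.int64)
        rewire_kernel(
            a,
            u,
            v,
            rng.integers(0, m, n_try),
            rng.integers(0, m, n_try),
            rng.integers(0, 2, n_try),
        )
        cps[i], lps[i], _ = cp_lp_kernel(a)
    return float(cps.mean()), float(lps.mean())


def small_world_index(
    g: BinaryGraph,
    n_nulls: int = 100,
    seed: int = 0,
    n_swap_per_edge: int = 10,
) -> SmallWorldResult:
    """Cp, Lp and sigma of one graph against its rewired-null ensemble."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    cp, lp, frac = _cp_lp(g.adjacency)
    if not np.isfinite(lp):
        raise ValueError("no reachable pairs: path length undefined")
    rng = np.random.default_rng(seed)
    cp_rand, lp_rand = _null_ensemble_means(
        g.adjacency, g.edge_list(), n_nulls, n_swap_per_edge, rng
    )
    if cp_rand <= 0:
        raise ValueError(
            f"null ensemble has zero mean clustering (n={g.n_nodes}, "
            f"m={g.n_edges}, n_nulls={n_nulls}): sigma undefined"
        )
    if lp_rand <= 0 or not np.isfinite(lp_rand):
        raise ValueError("null ensemble path length undefined")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return SmallWorldResult(
        density=g.density,
        cp=cp,
        lp=lp,
        cp_rand_mean=cp_rand,
        lp_rand_mean=lp_rand,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        n_nulls=n_nulls,
        seed=int(seed),
        frac_unreachable_pairs=frac,
    )


def nodal_centrality(g: BinaryGraph, kind: str = "degree") -> np.ndarray:
    """Per-node centrality.

    degree: degree / (N - 1), in [0, 1].
    betweenness: shortest-path betweenness normalized by (N-1)(N-2)/2.
    """
    n = g.n_nodes
    if kind == "degree":
        return g.degrees / (n - 1)
    if kind == "betweenness":
        import igraph as ig

        graph = ig.Graph(n, [tuple(e) for e in g.edge_list()])
        bc = np.asarray(graph.betweenness(), dtype=float)
        scale = (n - 1) * (n - 2) / 2.0
        return bc / scale if scale > 0 else bc
    raise ValueError(f"unknown centrality kind {kind!r}")


def metric_curves(
    graphs: Sequence[BinaryGraph],
    n_nulls: int = 100,
    seed: int = 0,
    n_swap_per_edge: int = 10,
    centrality_kind: str = "degree",
) -> tuple[list[SmallWorldResult], np.ndarray]:
    """Small-world metrics and nodal centrality at every density.

    Null seeds are derived per density from ``seed`` via SeedSequence
    spawning, so any single density can be recomputed independently.
    Returns (results, centralities) with centralities of shape
    (n_densities, N).
    """
    if centrality_kind not in CENTRALITY_KINDS:
        raise ValueError(f"unknown centrality kind {centrality_kind!r}")
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(graphs))
    results: list[SmallWorldResult] = []
    cents = np.empty((len(graphs), graphs[0].n_nodes if graphs else 0))
    for i, g in enumerate(graphs):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        results.append(
            small_world_index(
                g, n_nulls=n_nulls, seed=child_seed, n_swap_per_edge=n_swap_per_edge
            )
        )
        cents[i] = nodal_centrality(g, kind=centrality_kind)
    return results, cents
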