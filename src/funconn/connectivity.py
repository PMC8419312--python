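"""From regional time series to binarized correlation networks.

The continuous functional network is the matrix of pairwise product-moment
correlations between regional signals. Binary graphs are obtained by
proportional (density) thresholding: at density d the round(d * N(N-1)/2)
largest positive correlations become edges, so every subject's graph has
the same edge count at a given density before metrics are compared.

Negative correlations never become edges under the default policy; an
absolute-value mode is available via ``use_absolute=True``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datatypes import (
    BinaryGraph,
    ConnectivityMatrix,
    ConstantRegionError,
    ROITimeSeries,
    expected_edge_count,
)


def compute_correlation_matrix(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional signals."""
    sd = ts.values.std(axis=0)
    const = np.flatnonzero(sd == 0.0)
    if const.size:  # unreachable through a valid ROITimeSeries; guards raw use
        names = ", ".join(ts.roi_labels[i] for i in const[:5])
        raise ConstantRegionError(f"constant signal in region(s): {names}")
    c = np.corrcoef(ts.values.T)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, roi_labels=list(ts.roi_labels))


def _ranked_pairs(
    c: ConnectivityMatrix, use_absolute: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Upper-triangle pairs ordered by (weight desc, i asc, j asc)."""
    n = c.n_rois
    iu, ju = np.triu_indices(n, k=1)
    w = c.values[iu, ju]
    if use_absolute:
        w = np.abs(w)
    # row-major upper-triangle order is (i asc, j asc); a stable sort on -w
    # therefore breaks ties exactly by (smaller i, then smaller j)
    order = np.argsort(-w, kind="stable")
    n_available = int((w > 0).sum())
    return iu[order], ju[order], w[order], n_available


def threshold_by_density(
    c: ConnectivityMatrix, density: float, use_absolute: bool = False
) -> BinaryGraph:
    """Keep the k strongest positive correlations, k = round(d * N(N-1)/2).

    Rounding is half-away-from-zero. Ties at the cutoff are broken by the
    lexicographic order of the node pair, which makes the graph a pure
    function of the matrix.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = c.n_rois
    k = expected_edge_count(density, n)
    iu, ju, w, n_available = _ranked_pairs(c, use_absolute)
    if k > n_available:
        raise ValueError(
            f"density {density} requires {k} edges but only "
            f"{n_available} {'non-zero' if use_absolute else 'positive'} "
            "correlations are available"
        )
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[:k], ju[:k]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density, roi_labels=list(c.roi_labels))


def graphs_across_densities(
    c: ConnectivityMatrix,
    densities: Sequence[float],
    use_absolute: bool = False,
) -> list[BinaryGraph]:
    """One binary graph per density; graphs are nested by construction."""
    d = np.asarray(list(densities), dtype=float)
    if d.size == 0:
        raise ValueError("empty density grid")
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    n = c.n_rois
    iu, ju, w, n_available = _ranked_pairs(c, use_absolute)
    graphs = []
    for dens in d:
        k = expected_edge_count(dens, n)
        if k > n_available:
            raise ValueError(
                f"density {dens} requires {k} edges but only "
                f"{n_available} are available"
            )
        adj = np.zeros((n, n), dtype=bool)
        adj[iu[:k], ju[:k]] = True
        adj |= adj.T
        graphs.append(
            BinaryGraph(adjacency=adj, density=float(dens), roi_labels=list(c.roi_labels))
        )
    return graphs


def default_density_grid(
    low: float = 0.10, high: float = 0.50, step: float = 0.01
) -> np.ndarray:
    """Integer-percent density grid, by default 10% to 50% in 1% steps."""
    lo = int(round(low * 100))
    hi = int(round(high * 100))
    st = int(round(step * 100))
    if st <= 0 or lo <= 0 or hi > 100 or lo > hi:
        raise ValueError("invalid density grid bounds")
    return np.arange(lo, hi + 1, st) / 100.0
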