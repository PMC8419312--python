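"""Core value objects shared by the pipeline stages.

Each type validates its own invariants on construction so that downstream
stages can assume well-formed inputs: time series have no constant regions,
connectivity matrices are symmetric correlation matrices, and binary graphs
carry exactly the edge count implied by their density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GROUPS = ("HC", "PD_nICD", "PD_ICD")

#: The seven cortical networks of the 7-network parcellation scheme.
SEVEN_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)


class ConstantRegionError(ValueError):
    """A region's signal has zero variance, so correlations are undefined."""


@dataclass
class ROITimeSeries:
    """One subject's regional time series: T timepoints x N regions."""

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 timepoints, got {t}")
        if len(self.roi_labels) != n:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {n} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        sd = self.values.std(axis=0)
        const = np.flatnonzero(sd == 0.0)
        if const.size:
            names = ", ".join(self.roi_labels[i] for i in const[:5])
            raise ConstantRegionError(
                f"constant signal in region(s): {names}"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """N x N product-moment correlation matrix over regions."""

    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_labels) != n:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("connectivity matrix must have unit diagonal")
        if self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def expected_edge_count(density: float, n_nodes: int) -> int:
    """Edge count at a proportional density, rounded half away from zero."""
    m_max = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * m_max + 0.5))


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph at a fixed edge density."""

    adjacency: np.ndarray
    density: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not (0 < self.density <= 1):
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency has self-loops")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not self.roi_labels:
            self.roi_labels = [f"node_{i + 1}" for i in range(n)]
        elif len(self.roi_labels) != n:
            raise ValueError("label count does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of 0-based node pairs, i < j, lexicographic order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return np.column_stack((iu[0][mask], iu[1][mask]))


@dataclass
class SmallWorldResult:
    """Small-world quantities of one graph at one density.

    gamma = cp / cp_rand_mean, lam = lp / lp_rand_mean and
    sigma = gamma / lam, with the null means taken over an ensemble of
    degree-preserving rewired graphs.
    """

    density: float
    cp: float
    lp: float
    cp_rand_mean: float
    lp_rand_mean: float
    gamma: float
    lam: float
    sigma: float
    n_nulls: int
    seed: int
    frac_unreachable_pairs: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.cp_rand_mean <= 0 or self.lp_rand_mean <= 0:
            raise ValueError("null means must be positive")
        if not np.isclose(self.sigma * self.lam, self.gamma, rtol=1e-9):
            raise ValueError("sigma * lam must equal gamma")


@dataclass
class GroundTruthRecord:
    """Planted topology of one simulated subject, for recovery tests."""

    subject_id: str
    group: str
    true_adjacency: np.ndarray
    true_cp: float
    true_lp: float

    def __post_init__(self) -> None:
        self.true_adjacency = np.asarray(self.true_adjacency, dtype=bool)
        if np.any(np.diag(self.true_adjacency)):
            raise ValueError("ground-truth adjacency has self-loops")
        if not np.array_equal(self.true_adjacency, self.true_adjacency.T):
            raise ValueError("ground-truth adjacency must be symmetric")
        if not (0.0 <= self.true_cp <= 1.0):
            raise ValueError("true_cp must be in [0, 1]")


@dataclass
class GroupComparison:
    """One two-tailed group test: a metric at a density, or one node."""

    target: str  # cp | lp | sigma | nodal
    density: float | str  # density value, or "auc" for density-averaged
    statistic: float
    p_two_tailed: float
    direction: str  # A_greater | B_greater
    test_kind: str  # t | permutation | anova | chisq
    roi_index: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.direction not in ("A_greater", "B_greater"):
            raise ValueError(f"unknown direction {self.direction!r}")


def subject_seed(base_seed: int, group: str, index: int) -> np.random.SeedSequence:
    """Stable per-subject seed stream.

    Mixes the cohort seed with a CRC32 of ``"group:index"`` so that
    subjects draw from non-overlapping streams and any subject can be
    regenerated in isolation.
    """
    import zlib

    tag = zlib.crc32(f"{group}:{index}".encode())
    return np.random.SeedSequence([int(base_seed), tag])
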