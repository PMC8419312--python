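"""Synthetic resting-state cohorts with known network ground truth.

The restricted nature of the original imaging data means the pipeline is
exercised on simulated cohorts: each subject gets a planted graph topology
(Watts–Strogatz by default), the graph induces a correlation structure,
and a stationary multivariate Gaussian AR(1) process generates BOLD-like
regional time series at the study's acquisition length (210 volumes,
TR = 2.4 s).

The planted group difference is the Watts–Strogatz rewiring probability:
lower rewiring gives higher clustering and longer paths. Group defaults
place PD_ICD (0.05) above PD_nICD (0.30) in both Cp and Lp, with HC (0.15)
in between, matching the direction of the reported group effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    SEVEN_NETWORKS,
    GroundTruthRecord,
    ROITimeSeries,
    subject_seed,
)
from .metrics import _cp_lp

TOPOLOGIES = ("small_world", "random", "lattice", "modular")

#: Retry budget for redrawing a disconnected base graph.
CONNECTIVITY_RETRIES = 100

#: Eigenvalue floor used when repairing an indefinite graph covariance.
SPD_EPS = 1e-3


@dataclass
class SyntheticCohortSpec:
    """Parameters of a simulated three-group cohort.

    Defaults reproduce the study conditions: 16 HC / 18 PD_nICD /
    18 PD_ICD subjects, 100 regions, 210 volumes at TR 2.4 s, with the
    group difference planted through ``rewire_prob``.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 16, "PD_nICD": 18, "PD_ICD": 18}
    )
    n_rois: int = 100
    n_volumes: int = 210
    tr_seconds: float = 2.4
    base_topology: str = "small_world"
    lattice_degree: int = 10
    rewire_prob: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.15, "PD_nICD": 0.30, "PD_ICD": 0.05}
    )
    coupling: float = 0.4
    global_corr: float = 0.1
    ar_coeff: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("need at least 3 regions")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.base_topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.base_topology!r}")
        if self.lattice_degree % 2 or self.lattice_degree <= 0:
            raise ValueError("lattice_degree must be a positive even integer")
        if self.lattice_degree >= self.n_rois:
            raise ValueError("lattice_degree must be smaller than n_rois")
        if not (0 < self.coupling < 1):
            raise ValueError("coupling must lie in (0, 1)")
        if not (0 <= self.global_corr < self.coupling):
            raise ValueError("global_corr must lie in [0, coupling)")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g} has non-positive size {n}")
        for g in self.group_sizes:
            if g not in self.rewire_prob:
                raise ValueError(f"no rewire_prob for group {g}")
            p = self.rewire_prob[g]
            if not (0 <= p <= 1):
                raise ValueError(f"rewire_prob[{g}]={p} outside [0, 1]")

    def with_groups(self, **sizes: int) -> "SyntheticCohortSpec":
        return replace(self, group_sizes=dict(sizes))


def make_parcellation(n_rois: int) -> pd.DataFrame:
    """Deterministic 7-network parcellation label table.

    Mirrors the naming convention of the 100-parcel, 7-network cortical
    atlas ("7Networks_<hemi>_<network>_<k>"); regions are split evenly
    between hemispheres and cycled over the seven networks. Indices are
    1-based.
    """
    rows = []
    n_lh = n_rois // 2
    counters: dict[tuple[str, str], int] = {}
    for i in range(n_rois):
        hemi = "LH" if i < n_lh else "RH"
        net = SEVEN_NETWORKS[i % len(SEVEN_NETWORKS)]
        counters[(hemi, net)] = counters.get((hemi, net), 0) + 1
        rows.append(
            {
                "index": i + 1,
                "label": f"7Networks_{hemi}_{net}_{counters[(hemi, net)]}",
                "network": net,
            }
        )
    return pd.DataFrame(rows)


def _draw_base_graph(
    spec: SyntheticCohortSpec, rewire_p: float, seed_int: int
) -> nx.Graph:
    n, k = spec.n_rois, spec.lattice_degree
    if spec.base_topology == "small_world":
        return nx.watts_strogatz_graph(n, k, rewire_p, seed=seed_int)
    if spec.base_topology == "lattice":
        return nx.watts_strogatz_graph(n, k, 0.0, seed=seed_int)
    if spec.base_topology == "random":
        return nx.gnm_random_graph(n, n * k // 2, seed=seed_int)
    # modular: stochastic block model with 5 equal blocks and a 10:1
    # within/between density ratio, expected degree matched to k
    n_blocks = 5
    sizes = [n // n_blocks] * n_blocks
    sizes[-1] += n - sum(sizes)
    within = sizes[0] - 1 + (n - sizes[0]) / 10.0
    p_in = min(0.95, k / within)
    p_out = p_in / 10.0
    p = [
        [p_in if a == b else p_out for b in range(n_blocks)]
        for a in range(n_blocks)
    ]
    return nx.stochastic_block_model(sizes, p, seed=seed_int)


def generate_subject_graph(
    spec: SyntheticCohortSpec, group: str, seed: int | np.random.SeedSequence
) -> GroundTruthRecord:
    """Draw one connected subject graph from the group's topology.

    Redraws up to ``CONNECTIVITY_RETRIES`` times if the sample is
    disconnected; silent densification would bias clustering, so
    exhaustion is a hard error naming the parameters.
    """
    if group not in spec.rewire_prob:
        raise ValueError(f"unknown group {group!r}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    rewire_p = spec.rewire_prob[group]
    draw_seeds = ss.generate_state(CONNECTIVITY_RETRIES)
    for attempt in range(CONNECTIVITY_RETRIES):
        g = _draw_base_graph(spec, rewire_p, int(draw_seeds[attempt] % (2**31)))
        if nx.is_connected(g):
            adj = nx.to_numpy_array(g, nodelist=range(spec.n_rois)) > 0
            cp, lp, _ = _cp_lp(adj)
            return GroundTruthRecord(
                subject_id="",
                group=group,
                true_adjacency=adj,
                true_cp=cp,
                true_lp=lp,
            )
    raise RuntimeError(
        f"no connected {spec.base_topology} graph in "
        f"{CONNECTIVITY_RETRIES} draws (n_rois={spec.n_rois}, "
        f"lattice_degree={spec.lattice_degree}, rewire_prob={rewire_p})"
    )


def graph_to_covariance(
    adjacency: np.ndarray,
    coupling: float,
    global_corr: float = 0.0,
    eps: float = SPD_EPS,
) -> np.ndarray:
    """Correlation-form covariance induced by a graph.

    Builds S = delta * I + coupling * A + global_corr * (J - I), where J
    is the all-ones matrix: edges couple at ``coupling`` on top of a
    uniform background of ``global_corr`` shared by every pair (the
    analogue of the global BOLD component that makes empirical
    resting-state correlation distributions predominantly positive).
    The diagonal load delta is chosen adaptively: 1 when the matrix is
    already safely positive definite, otherwise just large enough that
    the smallest eigenvalue keeps a 5% margin. After rescaling to unit
    diagonal, edges carry (coupling+global_corr)/delta and non-edges
    global_corr/delta, so edges strictly exceed non-edges. Eigenvalue
    flooring at ``eps`` remains as a last-resort repair.
    """
    if not (0 < coupling < 1):
        raise ValueError("coupling must lie in (0, 1)")
    if not (0 <= global_corr < coupling):
        raise ValueError("global_corr must lie in [0, coupling)")
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    off = coupling * a + global_corr * (np.ones((n, n)) - np.eye(n))
    lam_min = float(np.linalg.eigvalsh(off)[0])
    delta = max(1.0, max(0.0, -lam_min) / 0.95)
    s = delta * np.eye(n) + off
    w = np.linalg.eigvalsh(s)
    if w[0] <= eps:  # safety net; unreachable for the adaptive delta
        w_full, v = np.linalg.eigh(s)
        s = (v * np.maximum(w_full, eps)) @ v.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    s = (s + s.T) / 2.0
    w_min = float(np.linalg.eigvalsh(s)[0])
    if w_min <= 0:
        raise ValueError(
            f"covariance not repairable: smallest eigenvalue {w_min:.3e}"
        )
    return s


def simulate_timeseries(
    cov: np.ndarray,
    n_volumes: int,
    ar_coeff: float = 0.3,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Stationary multivariate Gaussian AR(1) draw, T x N.

    x_t = phi * x_{t-1} + e_t with e_t ~ N(0, noise_sd^2 * cov); the
    initial state is drawn from the stationary distribution, so the
    process needs no burn-in and the stationary correlation structure
    equals that of ``cov``.
    """
    if not (0 <= ar_coeff < 1):
        raise ValueError("ar_coeff must lie in [0, 1): process must be stationary")
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    chol = np.linalg.cholesky(cov)  # raises if not SPD
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_volumes, n)) @ (noise_sd * chol).T
    x = np.empty((n_volumes, n))
    x[0] = eps[0] / np.sqrt(1.0 - ar_coeff**2)
    for t in range(1, n_volumes):
        x[t] = ar_coeff * x[t - 1] + eps[t]
    return x


@dataclass
class SyntheticCohort:
    """Generated subjects plus their planted ground truth."""

    spec: SyntheticCohortSpec
    subjects: list[ROITimeSeries]
    ground_truth: list[GroundTruthRecord]
    parcellation: pd.DataFrame

    def __iter__(self) -> Iterator[tuple[ROITimeSeries, GroundTruthRecord]]:
        return iter(zip(self.subjects, self.ground_truth))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group(self, name: str) -> list[ROITimeSeries]:
        return [s for s in self.subjects if s.group == name]


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate every subject of the cohort, reproducibly from spec.seed.

    Each subject's randomness comes from an independent stream mixed from
    (spec.seed, group, subject index), so single subjects can be
    regenerated without running the cohort.
    """
    parcellation = make_parcellation(spec.n_rois)
    labels = list(parcellation["label"])
    subjects: list[ROITimeSeries] = []
    records: list[GroundTruthRecord] = []
    for group in spec.group_sizes:
        for idx in range(spec.group_sizes[group]):
            ss = subject_seed(spec.seed, group, idx)
            graph_ss, ts_ss = ss.spawn(2)
            record = generate_subject_graph(spec, group, graph_ss)
            sid = f"{group}_{idx + 1:02d}"
            record.subject_id = sid
            cov = graph_to_covariance(
                record.true_adjacency, spec.coupling, spec.global_corr
            )
            values = simulate_timeseries(
                cov,
                spec.n_volumes,
                ar_coeff=spec.ar_coeff,
                noise_sd=spec.noise_sd,
                seed=ts_ss,
            )
            subjects.append(
                ROITimeSeries(
                    values=values, roi_labels=labels, subject_id=sid, group=group
                )
            )
            records.append(record)
    return SyntheticCohort(
        spec=spec, subjects=subjects, ground_truth=records, parcellation=parcellation
    )
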