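"""Model and results objects for the group connectome analysis.

``ConnectomeGroupAnalysis`` is constructed from subject-level regional
time series (real or simulated) and analysis settings; ``fit`` runs the
full pipeline — correlation network, proportional thresholding across the
density grid, small-world metrics against rewired-null ensembles, nodal
centrality — and returns a ``ConnectomeGroupResults`` carrying tidy
DataFrames plus the group-comparison and reporting machinery.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .connectivity import (
    compute_correlation_matrix,
    default_density_grid,
    graphs_across_densities,
)
from .datatypes import ROITimeSeries
from .metrics import CENTRALITY_KINDS, metric_curves
from .stats import (
    compare_metric_curves,
    compare_nodal_centrality,
    nodal_report,
    significant_bands,
)

METRICS = ("cp", "lp", "sigma")

_CURVE_COLUMNS = [
    "subject",
    "group",
    "density",
    "cp",
    "lp",
    "cp_rand_mean",
    "lp_rand_mean",
    "gamma",
    "lam",
    "sigma",
    "frac_unreachable",
]


class ConnectomeGroupAnalysis:
    """Group comparison of density-thresholded functional connectomes.

    Parameters
    ----------
    subjects
        Regional time series, one per subject, each carrying a group
        label. All subjects must share the same region set.
    parcellation
        Table with 1-based ``index``, ``label`` and ``network`` columns.
        If omitted, a generic one is built from the subjects' labels.
    densities
        Strictly increasing edge-density grid (default 0.10-0.50 in 0.01
        steps).
    n_nulls, n_swap_per_edge
        Size of the degree-preserving null ensemble per graph and the
        number of swap attempts per edge per null.
    centrality
        "degree" (default) or "betweenness".
    test_kind
        "t" (pooled-variance, default) or "permutation".
    """

    def __init__(
        self,
        subjects: Sequence[ROITimeSeries],
        parcellation: pd.DataFrame | None = None,
        densities: Sequence[float] | None = None,
        n_nulls: int = 100,
        n_swap_per_edge: int = 10,
        centrality: str = "degree",
        test_kind: str = "t",
        alpha: float = 0.05,
        use_absolute: bool = False,
    ) -> None:
        if len(subjects) < 1:
            raise ValueError("need at least one subject")
        labels = subjects[0].roi_labels
        for s in subjects:
            if s.roi_labels != labels:
                raise ValueError(
                    f"subject {s.subject_id}: region labels differ from the cohort's"
                )
        if centrality not in CENTRALITY_KINDS:
            raise ValueError(f"unknown centrality kind {centrality!r}")
        self.subjects = list(subjects)
        if parcellation is None:
            parcellation = pd.DataFrame(
                {
                    "index": np.arange(1, len(labels) + 1),
                    "label": labels,
                    "network": "unknown",
                }
            )
        if list(parcellation["label"]) != labels:
            raise ValueError("parcellation labels do not match subject labels")
        self.parcellation = parcellation.reset_index(drop=True)
        self.densities = (
            default_density_grid()
            if densities is None
            else np.asarray(list(densities), dtype=float)
        )
        self.n_nulls = int(n_nulls)
        self.n_swap_per_edge = int(n_swap_per_edge)
        self.centrality = centrality
        self.test_kind = test_kind
        self.alpha = float(alpha)
        self.use_absolute = bool(use_absolute)

    # ------------------------------------------------------------ constructors

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ConnectomeGroupAnalysis":
        """Build from a :class:`~funconn.synthetic.SyntheticCohort`."""
        kwargs.setdefault("parcellation", cohort.parcellation)
        return cls(cohort.subjects, **kwargs)

    @classmethod
    def from_spec(cls, spec, **kwargs) -> "ConnectomeGroupAnalysis":
        """Generate a synthetic cohort from a spec and build the model."""
        from .synthetic import generate_cohort

        return cls.from_cohort(generate_cohort(spec), **kwargs)

    @classmethod
    def from_directory(cls, indir: str | Path, **kwargs) -> "ConnectomeGroupAnalysis":
        """Read subject TSVs plus parcellation.tsv from a directory."""
        from .io import read_cohort_dir

        subjects, parcellation = read_cohort_dir(indir)
        kwargs.setdefault("parcellation", parcellation)
        return cls(subjects, **kwargs)

    # ------------------------------------------------------------------- fit

    def fit(self, seed: int = 0, verbose: bool = False) -> "ConnectomeGroupResults":
        """Run the pipeline for every subject.

        Null-model seeds are derived per subject by mixing ``seed`` with a
        CRC32 of the subject id, so the fit is reproducible and
        subject-order independent.
        """
        curve_rows = []
        cent_rows = []
        for s in self.subjects:
            c = compute_correlation_matrix(s)
            graphs = graphs_across_densities(
                c, self.densities, use_absolute=self.use_absolute
            )
            sub_seed = int(
                np.random.SeedSequence(
                    [int(seed), zlib.crc32(s.subject_id.encode())]
                ).generate_state(1)[0]
                % (2**31)
            )
            results, cents = metric_curves(
                graphs,
                n_nulls=self.n_nulls,
                seed=sub_seed,
                n_swap_per_edge=self.n_swap_per_edge,
                centrality_kind=self.centrality,
            )
            for r in results:
                curve_rows.append(
                    (
                        s.subject_id,
                        s.group,
                        r.density,
                        r.cp,
                        r.lp,
                        r.cp_rand_mean,
                        r.lp_rand_mean,
                        r.gamma,
                        r.lam,
                        r.sigma,
                        r.frac_unreachable_pairs,
                    )
                )
            for di, d in enumerate(self.densities):
                for ni in range(len(self.parcellation)):
                    cent_rows.append(
                        (s.subject_id, s.group, float(d), ni + 1, cents[di, ni])
                    )
            if verbose:
                print(f"fitted {s.subject_id}")
        curves = pd.DataFrame(curve_rows, columns=_CURVE_COLUMNS)
        centrality = pd.DataFrame(
            cent_rows, columns=["subject", "group", "density", "roi_index", "centrality"]
        )
        centrality = centrality.merge(
            self.parcellation.rename(columns={"index": "roi_index", "label": "roi_label"}),
            on="roi_index",
            how="left",
        )
        return ConnectomeGroupResults(self, curves, centrality, int(seed))


class ConnectomeGroupResults:
    """Fitted per-subject metric curves, centralities and group tests."""

    def __init__(
        self,
        model: ConnectomeGroupAnalysis,
        curves: pd.DataFrame,
        centrality: pd.DataFrame,
        seed: int,
    ) -> None:
        self.model = model
        self.curves = curves
        self.centrality = centrality
        self.seed = seed

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.model.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def group_pairs(self) -> list[tuple[str, str]]:
        g = self.groups
        return [(a, b) for i, a in enumerate(g) for b in g[i + 1 :]]

    # ---------------------------------------------------------- comparisons

    def _metric_matrix(self, metric: str, group: str) -> np.ndarray:
        sub = self.curves[self.curves["group"] == group]
        pivot = sub.pivot(index="subject", columns="density", values=metric)
        pivot = pivot[np.sort(pivot.columns)]
        return pivot.to_numpy()

    def compare_curves(
        self, metric: str, group_a: str, group_b: str, **kwargs
    ) -> pd.DataFrame:
        """Per-density two-tailed test of one metric between two groups."""
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        kwargs.setdefault("test_kind", self.model.test_kind)
        kwargs.setdefault("alpha", self.model.alpha)
        kwargs.setdefault("seed", self.seed)
        out = compare_metric_curves(
            self._metric_matrix(metric, group_a),
            self._metric_matrix(metric, group_b),
            self.model.densities,
            metric,
            **kwargs,
        )
        out.insert(0, "group_b", group_b)
        out.insert(0, "group_a", group_a)
        return out

    def _centrality_matrix(self, group: str, density) -> np.ndarray:
        sub = self.centrality[self.centrality["group"] == group]
        if density == "auc":
            sub = sub.groupby(["subject", "roi_index"], as_index=False)[
                "centrality"
            ].mean()
        else:
            sub = sub[np.isclose(sub["density"], float(density))]
        pivot = sub.pivot(index="subject", columns="roi_index", values="centrality")
        return pivot[np.sort(pivot.columns)].to_numpy()

    def compare_nodal(
        self, group_a: str, group_b: str, density="auc", **kwargs
    ) -> pd.DataFrame:
        """Per-node centrality test; ``density`` is a grid value or "auc".

        "auc" (default) averages each subject's nodal centrality over the
        density grid before testing, summarizing the whole curve.
        """
        kwargs.setdefault("test_kind", self.model.test_kind)
        kwargs.setdefault("alpha", self.model.alpha)
        kwargs.setdefault("seed", self.seed)
        out = compare_nodal_centrality(
            self._centrality_matrix(group_a, density),
            self._centrality_matrix(group_b, density),
            self.model.parcellation,
            **kwargs,
        )
        out.insert(0, "group_b", group_b)
        out.insert(0, "group_a", group_a)
        return out

    # ------------------------------------------------------------- reporting

    def summary(self) -> str:
        """Text report: sigma regime, significant bands, nodal effects."""
        lines = [
            "Functional connectome group analysis "
            f"(funconn {_pkg_version})",
            f"subjects: {len(self.model.subjects)} "
            + " ".join(
                f"{g}={sum(s.group == g for s in self.model.subjects)}"
                for g in self.groups
            ),
            f"densities: {self.model.densities[0]:.2f}-"
            f"{self.model.densities[-1]:.2f} "
            f"({len(self.model.densities)} steps), "
            f"nulls per graph: {self.model.n_nulls}, "
            f"centrality: {self.model.centrality}, "
            f"test: {self.model.test_kind}, alpha: {self.model.alpha}",
            "",
            f"min sigma over all subjects/densities: "
            f"{self.curves['sigma'].min():.3f} "
            f"(small-world regime iff > 1)",
            "",
        ]
        for a, b in self.group_pairs():
            lines.append(f"-- {a} vs {b} --")
            for metric in METRICS:
                comp = self.compare_curves(metric, a, b)
                bands = significant_bands(comp)
                if bands:
                    txt = ", ".join(
                        f"{lo * 100:.0f}-{hi * 100:.0f}%" if hi > lo else f"{lo * 100:.0f}%"
                        for lo, hi in bands
                    )
                else:
                    txt = "none"
                mean_a = self.curves.loc[self.curves.group == a, metric].mean()
                mean_b = self.curves.loc[self.curves.group == b, metric].mean()
                lines.append(
                    f"  {metric:<5} mean {mean_a:.3f} vs {mean_b:.3f}; "
                    f"significant densities: {txt}"
                )
            lines.append(f"  nodal centrality ({self.model.centrality}, density-averaged):")
            lines.append(
                "    "
                + nodal_report(self.compare_nodal(a, b), a, b).replace("\n", "\n    ")
            )
            lines.append("")
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence

    def save(self, outdir: str | Path, config: dict | None = None) -> Path:
        """Write curves, centralities, all pairwise contrasts and a manifest."""
        from .io import write_manifest

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curves.to_csv(
            outdir / "metric_curves.csv", index=False, float_format="%.10g",
            lineterminator="\n",
        )
        self.centrality.to_csv(
            outdir / "nodal_centrality.csv", index=False, float_format="%.10g",
            lineterminator="\n",
        )
        for a, b in self.group_pairs():
            tag = f"{a}_vs_{b}"
            parts = [self.compare_curves(m, a, b) for m in METRICS]
            pd.concat(parts, ignore_index=True).to_csv(
                outdir / f"contrast_{tag}_curves.csv", index=False,
                float_format="%.10g", lineterminator="\n",
            )
            self.compare_nodal(a, b).to_csv(
                outdir / f"contrast_{tag}_nodal.csv", index=False,
                float_format="%.10g", lineterminator="\n",
            )
        (outdir / "report.txt").write_text(self.summary() + "\n")
        meta = dict(config or {})
        meta.setdefault("seed", self.seed)
        meta.setdefault("funconn_version", _pkg_version)
        write_manifest(outdir, meta)
        return outdir

    def plot_curves(self, metric: str = "cp", ax=None):
        """Group mean +/- SEM of a metric across densities."""
        from .plotting import plot_metric_curves

        return plot_metric_curves(self, metric=metric, ax=ax)
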