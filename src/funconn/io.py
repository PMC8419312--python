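"""Plain-text file formats tying the pipeline stages together.

Everything is TSV/CSV/JSON: subject time series are T x N TSV files with
a header row of region labels; parcellation tables are 1-based TSVs of
(index, label, network); graphs are two-column 1-based edge-list CSVs
with a JSON sidecar; per-subject metric curves and nodal centralities are
long-format CSVs. A run manifest records a sha256 for every output.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import GROUPS, BinaryGraph, ROITimeSeries
from .synthetic import SyntheticCohort


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


# ---------------------------------------------------------------- time series


def write_timeseries_tsv(ts: ROITimeSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=ts.roi_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    return path


def read_timeseries_tsv(
    path: str | Path, subject_id: str = "", group: str = ""
) -> ROITimeSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 rows and 2 columns")
    bad = df.columns[~df.dtypes.apply(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        rows = [
            int(i) + 2  # +1 header, +1 one-based
            for col in bad
            for i in np.flatnonzero(pd.to_numeric(df[col], errors="coerce").isna())[:3]
        ]
        raise FormatError(f"{path}: non-numeric values (lines {sorted(set(rows))[:5]})")
    if not subject_id:
        subject_id = path.stem
    if not group:
        group = infer_group(subject_id)
    return ROITimeSeries(
        values=df.to_numpy(dtype=float),
        roi_labels=list(df.columns),
        subject_id=subject_id,
        group=group,
    )


def infer_group(subject_id: str) -> str:
    """Group from a subject id such as ``PD_ICD_03`` (longest-prefix match)."""
    for g in sorted(GROUPS, key=len, reverse=True):
        if subject_id.startswith(g):
            return g
    return ""


# ---------------------------------------------------------------- parcellation


def write_parcellation_tsv(parcellation: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    parcellation.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_parcellation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"index", "label", "network"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------- cohorts


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> list[Path]:
    """Write per-subject TSVs, the parcellation and ground-truth edges."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt_dir = outdir / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    written = [write_parcellation_tsv(cohort.parcellation, outdir / "parcellation.tsv")]
    for ts, record in cohort:
        written.append(write_timeseries_tsv(ts, outdir / f"{ts.subject_id}.tsv"))
        edges = np.argwhere(np.triu(record.true_adjacency, k=1)) + 1
        edf = pd.DataFrame(edges, columns=["node_i", "node_j"])
        p = gt_dir / f"{ts.subject_id}_edges.csv"
        edf.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
    return written


def read_cohort_dir(indir: str | Path) -> tuple[list[ROITimeSeries], pd.DataFrame]:
    """Read every subject TSV plus the parcellation from a directory."""
    indir = Path(indir)
    parc_path = indir / "parcellation.tsv"
    if not parc_path.exists():
        raise FormatError(f"missing parcellation table {parc_path}")
    parcellation = read_parcellation_tsv(parc_path)
    labels = list(parcellation["label"])
    subjects = []
    for p in sorted(indir.glob("*.tsv")):
        if p.name == "parcellation.tsv":
            continue
        ts = read_timeseries_tsv(p)
        if ts.roi_labels != labels:
            raise FormatError(
                f"{p}: region labels do not match the parcellation table"
            )
        subjects.append(ts)
    if not subjects:
        raise FormatError(f"no subject TSV files in {indir}")
    return subjects, parcellation


# ---------------------------------------------------------------- matrices & graphs


def write_connectivity_csv(
    values: np.ndarray, labels: list[str], path: str | Path
) -> Path:
    path = Path(path)
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, float_format="%.10g", lineterminator="\n")
    return path


def read_connectivity_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_graph_edgelist(g: BinaryGraph, path: str | Path) -> Path:
    """Two-column 1-based edge list CSV plus a ``.json`` sidecar."""
    path = Path(path)
    edges = g.edge_list() + 1
    pd.DataFrame(edges, columns=["node_i", "node_j"]).to_csv(
        path, index=False, lineterminator="\n"
    )
    sidecar = {
        "density": g.density,
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "roi_labels": g.roi_labels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")
    return path


def read_graph_edgelist(path: str | Path) -> BinaryGraph:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    n = meta["n_nodes"]
    adj = np.zeros((n, n), dtype=bool)
    e = df.to_numpy(dtype=int) - 1
    adj[e[:, 0], e[:, 1]] = True
    adj |= adj.T
    return BinaryGraph(
        adjacency=adj, density=meta["density"], roi_labels=meta["roi_labels"]
    )


# ---------------------------------------------------------------- published summaries


def load_demographics() -> pd.DataFrame:
    """Printed per-group summary statistics of the PPMI PD-ICD cohort."""
    with resources.files("funconn.data").joinpath(
        "ppmi_icd_demographics.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_sex_counts() -> pd.DataFrame:
    """Printed male:female counts per group of the PPMI PD-ICD cohort."""
    with resources.files("funconn.data").joinpath(
        "ppmi_icd_sex_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------- manifest


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path, config: dict, files: Iterable[str | Path] | None = None
) -> Path:
    """Record config plus a sha256 for every file under ``outdir``."""
    outdir = Path(outdir)
    if files is None:
        files = [p for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"]
    entries = {
        str(Path(p).relative_to(outdir)): sha256_of(p) for p in files
    }
    manifest = {"config": config, "files": entries}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
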