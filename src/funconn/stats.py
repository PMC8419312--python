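"""Group-level statistics.

Two families live here:

* summary-statistics tests used to reproduce the published cohort
  demographics table from its printed means/SDs/ns and contingency
  counts (one-way fixed-effects ANOVA, pooled-variance two-sample t,
  Pearson chi-square without continuity correction), and

* per-density / per-node two-tailed group comparisons of metric curves
  and nodal centralities, reported uncorrected at alpha = 0.05 by
  default (an FDR option is provided), with an optional label-permutation
  alternative to the pooled t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GroupComparison


@dataclass
class SummaryTestResult:
    statistic: float
    p_value: float
    df: tuple[float, ...]
    degenerate: bool = False


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> SummaryTestResult:
    """One-way fixed-effects ANOVA reconstructed from per-group summaries.

    Between-group SS from the group means and sizes, within-group SS from
    the group SDs; F on (k-1, N-k) degrees of freedom. Identical to the
    raw-data ANOVA because those sums of squares are sufficient.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = np.asarray(ns, dtype=float)
    if len(m) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(s < 0):
        raise ValueError("negative SD")
    k = len(m)
    total = n.sum()
    grand = (n * m).sum() / total
    ss_between = (n * (m - grand) ** 2).sum()
    ss_within = ((n - 1) * s**2).sum()
    df1, df2 = k - 1.0, total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return SummaryTestResult(0.0, 1.0, (df1, df2), degenerate=True)
        return SummaryTestResult(np.inf, 0.0, (df1, df2), degenerate=True)
    f = (ss_between / df1) / (ss_within / df2)
    return SummaryTestResult(float(f), float(sps.f.sf(f, df1, df2)), (df1, df2))


def ttest_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> SummaryTestResult:
    """Pooled-variance two-sample two-tailed t test from summaries."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a == 0.0 and sd_b == 0.0:
        df = (float(n_a + n_b - 2),)
        if mean_a == mean_b:
            return SummaryTestResult(0.0, 1.0, df, degenerate=True)
        return SummaryTestResult(np.inf, 0.0, df, degenerate=True)
    t, p = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return SummaryTestResult(float(t), float(p), (float(n_a + n_b - 2),))


def chisq_contingency(table: np.ndarray | Sequence[Sequence[int]]) -> SummaryTestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.min() < 0:
        raise ValueError("negative counts")
    if t.sum() <= 0:
        raise ValueError("empty contingency table")
    row_zero = np.flatnonzero(t.sum(axis=1) == 0)
    col_zero = np.flatnonzero(t.sum(axis=0) == 0)
    if row_zero.size or col_zero.size:
        raise ValueError(
            f"zero marginal: rows {row_zero.tolist()}, columns {col_zero.tolist()}"
        )
    res = sps.chi2_contingency(t, correction=False)
    return SummaryTestResult(float(res[0]), float(res[1]), (float(res[2]),))


def _direction(stat: float) -> str:
    return "A_greater" if stat > 0 else "B_greater"


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance t along axis 0 of two 2-D arrays."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), na + nb - 2)
    p = np.where(denom > 0, p, 1.0)
    return t, p


def _permutation_p(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed label-permutation test on the mean difference.

    p = (1 + #{|perm diff| >= |observed|}) / (n_perm + 1).
    """
    na = a.shape[0]
    pooled = np.vstack([a, b])
    obs = a.mean(axis=0) - b.mean(axis=0)
    count = np.zeros(obs.shape, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa = pooled[perm[:na]]
        pb = pooled[perm[na:]]
        count += np.abs(pa.mean(axis=0) - pb.mean(axis=0)) >= np.abs(obs) - 1e-15
    p = (1.0 + count) / (n_perm + 1.0)
    return obs, p


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def compare_metric_curves(
    values_a: np.ndarray,
    values_b: np.ndarray,
    densities: Sequence[float],
    metric: str,
    test_kind: str = "t",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-tailed group comparison of one metric at every density.

    ``values_a``/``values_b`` are (n_subjects, n_densities) arrays on the
    same density grid. Returns one row per density with the statistic,
    two-tailed p, direction and an (uncorrected by default) significance
    flag.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    d = np.asarray(list(densities), dtype=float)
    if a.shape[1] != d.size or b.shape[1] != d.size:
        raise ValueError("density grids of the two groups do not match")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if test_kind == "t":
        stat, p = _pooled_t(a, b)
    elif test_kind == "permutation":
        stat, p = _permutation_p(a, b, n_perm, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown test kind {test_kind!r}")
    p_eff = fdr_adjust(p) if fdr else p
    rows = [
        GroupComparison(
            target=metric,
            density=float(d[i]),
            statistic=float(stat[i]),
            p_two_tailed=float(p[i]),
            direction=_direction(float(stat[i])),
            test_kind=test_kind,
        )
        for i in range(d.size)
    ]
    out = pd.DataFrame(
        {
            "metric": metric,
            "density": d,
            "statistic": [r.statistic for r in rows],
            "p": [r.p_two_tailed for r in rows],
            "direction": [r.direction for r in rows],
            "significant": p_eff < alpha,
        }
    )
    return out


def compare_nodal_centrality(
    values_a: np.ndarray,
    values_b: np.ndarray,
    parcellation: pd.DataFrame,
    test_kind: str = "t",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-node two-tailed group test on centralities.

    ``values_a``/``values_b`` are (n_subjects, N) arrays; the
    parcellation table supplies 1-based index, label and network for each
    node. Rows at p < alpha partition into "A larger" / "A smaller".
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    n = len(parcellation)
    if a.shape[1] != n or b.shape[1] != n:
        raise ValueError("centrality tables do not match the parcellation")
    if test_kind == "t":
        stat, p = _pooled_t(a, b)
    elif test_kind == "permutation":
        stat, p = _permutation_p(a, b, n_perm, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown test kind {test_kind!r}")
    p_eff = fdr_adjust(p) if fdr else p
    return pd.DataFrame(
        {
            "roi_index": parcellation["index"].to_numpy(),
            "roi_label": parcellation["label"].to_numpy(),
            "network": parcellation["network"].to_numpy(),
            "statistic": stat,
            "p": p,
            "direction": [_direction(s) for s in stat],
            "significant": p_eff < alpha,
        }
    )


def nodal_report(comparison: pd.DataFrame, name_a: str, name_b: str) -> str:
    """Human-readable nodal table partitioned by direction of the effect."""
    lines = []
    for direction, title in (
        ("A_greater", f"{name_a} larger than {name_b}"),
        ("B_greater", f"{name_a} smaller than {name_b}"),
    ):
        sub = comparison[
            comparison["significant"] & (comparison["direction"] == direction)
        ].sort_values("p")
        lines.append(title)
        if sub.empty:
            lines.append("  (none)")
        for _, row in sub.iterrows():
            lines.append(
                f"  ROI {row.roi_index:>3}  {row.roi_label:<36} "
                f"{row.network:<12} p={row.p:.3f}"
            )
    return "\n".join(lines)


def significant_bands(comparison: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous density bands flagged significant, as (low, high) pairs."""
    sig = comparison.sort_values("density")
    bands: list[tuple[float, float]] = []
    start: float | None = None
    last: float = np.nan
    for d, s in zip(sig["density"], sig["significant"]):
        if s:
            if start is None:
                start = d
            last = d
        elif start is not None:
            bands.append((start, last))
            start = None
    if start is not None:
        bands.append((start, last))
    return bands
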