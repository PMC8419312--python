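"""Metric-vs-density curve plots with group significance markers."""

from __future__ import annotations

import numpy as np

_METRIC_LABELS = {
    "cp": "Clustering coefficient $C_p$",
    "lp": "Characteristic path length $L_p$",
    "sigma": "Small-world index $\\sigma$",
}


def plot_metric_curves(results, metric: str = "cp", ax=None, markers: bool = True):
    """Group mean +/- SEM curves; dots mark densities with p < alpha.

    ``results`` is a fitted :class:`~funconn.model.ConnectomeGroupResults`.
    Significance markers are drawn for each pairwise contrast just above
    the curves, one row per pair.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    curves = results.curves
    densities = results.model.densities
    for group in results.groups:
        sub = curves[curves["group"] == group]
        by_d = sub.groupby("density")[metric]
        mean = by_d.mean().reindex(densities)
        sem = (by_d.std(ddof=1) / np.sqrt(by_d.count())).reindex(densities)
        ax.plot(densities, mean, label=group, lw=1.5)
        ax.fill_between(densities, mean - sem, mean + sem, alpha=0.2)
    if markers:
        ymax = curves.groupby(["group", "density"])[metric].mean().max()
        offset = 0.03 * max(abs(ymax), 1e-9)
        for i, (a, b) in enumerate(results.group_pairs()):
            comp = results.compare_curves(metric, a, b)
            sig = comp.loc[comp["significant"], "density"].to_numpy()
            if sig.size:
                ax.plot(
                    sig,
                    np.full(sig.size, ymax + (i + 1) * offset),
                    linestyle="none",
                    marker="v",
                    markersize=4,
                    label=f"{a} vs {b} (p<{results.model.alpha:g})",
                )
    if metric == "sigma":
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("edge density")
    ax.set_ylabel(_METRIC_LABELS.get(metric, metric))
    ax.legend(fontsize=7)
    return ax
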