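"""Paper-style figures: score plots, correlation-loading circles, heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cpca import CPCAModel, CorrelationLoadings, score_plot_data

_STAGE_MARKERS = {"FW": "o", "SW": "^"}


def _scatter_by_group(ax, table: pd.DataFrame, xcol: str, ycol: str) -> None:
    groups = sorted(table["diet_group"].unique())
    cmap = plt.get_cmap("tab10")
    colors = {g: cmap(i % 10) for i, g in enumerate(groups)}
    for (g, s), sub in table.groupby(["diet_group", "stage"], observed=True):
        ax.scatter(sub[xcol], sub[ycol], c=[colors[g]],
                   marker=_STAGE_MARKERS.get(s, "s"), s=28,
                   label=f"{g} {s}", edgecolors="none", alpha=0.85)
    ax.axhline(0, lw=0.5, color="0.7")
    ax.axvline(0, lw=0.5, color="0.7")


def global_score_plot(
    model: CPCAModel, sample_meta: pd.DataFrame, path: str | Path,
    components: tuple[int, int] = (1, 2),
) -> None:
    table = score_plot_data(model, sample_meta, "global", components)
    fig, ax = plt.subplots(figsize=(6, 5))
    xcol, ycol = (f"PC{c}" for c in components)
    _scatter_by_group(ax, table, xcol, ycol)
    evs = model.ev_global
    ax.set_xlabel(f"{xcol} ({100 * evs.iloc[components[0] - 1]:.1f}%)")
    ax.set_ylabel(f"{ycol} ({100 * evs.iloc[components[1] - 1]:.1f}%)")
    ax.set_title("CPCA global scores")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def block_score_plots(
    model: CPCAModel, sample_meta: pd.DataFrame, path: str | Path,
    components: tuple[int, int] = (1, 2),
) -> None:
    labels = list(model.block_scores)
    fig, axes = plt.subplots(1, len(labels), figsize=(3.2 * len(labels), 3.4),
                             squeeze=False)
    xcol, ycol = (f"PC{c}" for c in components)
    for ax, lab in zip(axes[0], labels):
        table = score_plot_data(model, sample_meta, lab, components)
        _scatter_by_group(ax, table, xcol, ycol)
        ax.set_title(lab, fontsize=9)
        ax.set_xlabel(xcol, fontsize=8)
        ax.set_ylabel(ycol, fontsize=8)
    fig.suptitle("CPCA block scores")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_loading_plot(loadings: CorrelationLoadings, path: str | Path) -> None:
    """Correlation loadings with the 100% (r=1) and 50% (r=sqrt(0.5)) circles.

    The inner circle is drawn at radius sqrt(0.5): explained variance is the
    sum of squared correlations, so 50% EV corresponds to distance sqrt(0.5)
    from the origin.
    """
    c1, c2 = loadings.components[:2]
    x = loadings.correlations[f"r_PC{c1}"]
    y = loadings.correlations[f"r_PC{c2}"]
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="0.4", lw=1.0)
    r50 = np.sqrt(0.5)
    ax.plot(r50 * np.cos(theta), r50 * np.sin(theta), color="0.6", lw=0.8, ls="--")
    ax.scatter(x, y, s=10, alpha=0.7)
    ax.axhline(0, lw=0.5, color="0.8")
    ax.axvline(0, lw=0.5, color="0.8")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.set_xlabel(f"r(PC{c1})")
    ax.set_ylabel(f"r(PC{c2})")
    ax.set_title("Correlation loadings (outer 100%, inner 50% EV)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def da_heatmap(dataset, da_results: pd.DataFrame, path: str | Path) -> None:
    """Row-scaled heatmap of the flagged species' diet x stage cell means."""
    from .differential import heatmap_groups

    flagged = da_results.index[da_results["significant"]]
    meta = dataset.sample_meta
    logv = np.log2(dataset.abundance[flagged])
    cells = logv.groupby([meta["stage"], meta["diet_group"]], observed=True).mean()
    mat = cells.T
    mat.columns = [f"{s}|{g}" for s, g in mat.columns]
    labels, scaled = heatmap_groups(mat)
    order = labels.sort_values(kind="stable").index
    fig, ax = plt.subplots(figsize=(7, max(3, 0.12 * len(order))))
    im = ax.imshow(scaled.loc[order], aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(scaled.shape[1]))
    ax.set_xticklabels(scaled.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([f"{s} ({labels[s]})" for s in order], fontsize=4)
    fig.colorbar(im, ax=ax, label="row-scaled log2 abundance")
    ax.set_title("Differentially abundant species (row-scaled)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
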