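"""Figures: effect-size heatmap, effect time courses, PCA panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .multivariate import PCADiscrimination

__all__ = ["effect_heatmap", "time_course_plot", "pca_panel"]

_STARS = {"p<0.01": "**", "p<0.05": "*", "NS": ""}


def effect_heatmap(effects: pd.DataFrame, day: int | None = None,
                   out: str | Path | None = None, vmax: float = 60.0):
    """Species × descriptor heatmap of effect sizes at one imaging day.

    Cell color encodes the signed effect %, the annotation its significance
    category; defaults to the last imaging day within the treatment.
    """
    df = effects
    if day is None:
        in_treat = df[~df["post_treatment"]] if "post_treatment" in df else df
        day = int(in_treat["day"].max())
    df = df[df["day"] == day]
    pivot = df.pivot_table(index="descriptor", columns="species",
                           values="effect_size_percent", aggfunc="first")
    sig = df.pivot_table(index="descriptor", columns="species",
                         values="significance", aggfunc="first")
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.9 * pivot.shape[1], 0.6 + 0.3 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(dtype=float), cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = pivot.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, _STARS.get(sig.iat[i, j], ""), ha="center",
                        va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="effect size (%)")
    ax.set_title(f"Gradient effect sizes, day {day} (*p<0.05, **p<0.01)")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def time_course_plot(effects: pd.DataFrame, descriptors: list[str],
                     out: str | Path | None = None,
                     treatment_end: float | None = None):
    """Effect size vs day, one panel per descriptor, one line per species."""
    n = len(descriptors)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False)
    for ax, name in zip(axes[0], descriptors):
        sub = effects[effects["descriptor"] == name]
        for species, grp in sub.groupby("species"):
            grp = grp.sort_values("day")
            ax.plot(grp["day"], grp["effect_size_percent"], "-o",
                    ms=3, label=str(species))
            ns = grp[grp["significance"] == "NS"]
            ax.plot(ns["day"], ns["effect_size_percent"], "o", ms=5,
                    mfc="white", mec="grey")
        if treatment_end is not None:
            ax.axvline(treatment_end, ls=":", color="k", lw=1)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("day")
    axes[0][0].set_ylabel("effect size (%)")
    axes[0][-1].legend(fontsize=6)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def pca_panel(results: dict[str, PCADiscrimination],
              out: str | Path | None = None):
    """Grid of PC1/PC2 scatter plots, one per feature selection."""
    n = len(results)
    cols = min(3, n)
    rows = (n + cols - 1) // cols
    fig, axes = plt.subplots(rows, cols, figsize=(3.4 * cols, 3.0 * rows),
                             squeeze=False)
    for ax, (label, res) in zip(axes.ravel(), results.items()):
        for species, grp in res.scores.groupby("species"):
            ax.scatter(grp["PC1"], grp.get("PC2", 0), s=8, label=str(species))
        ev = res.explained_variance_ratio
        ax.set_title(f"{label} (sil {res.silhouette:.2f})", fontsize=9)
        ax.set_xlabel(f"PC1 {100 * ev[0]:.0f}%")
        if len(ev) > 1:
            ax.set_ylabel(f"PC2 {100 * ev[1]:.0f}%")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes.ravel()[0].legend(fontsize=6)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
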