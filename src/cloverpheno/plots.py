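"""Figure helpers: PCA biplots, Yr trajectories, trait histograms.

All functions return the matplotlib figure; callers decide where to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_TRAIT_COLORS = {"CC": "tab:green", "CH": "tab:blue", "CWSI": "tab:red"}


def biplot(pca_result, group_labels: pd.Series | None = None, components=(0, 1)):
    """Variables as arrows (colored by trait family), scores as points."""
    i, j = components
    fig, ax = plt.subplots(figsize=(7, 6))
    scores = pca_result.scores
    if group_labels is not None:
        labels = scores.index.to_series().map(group_labels.to_dict())
        for lab, sub in scores.groupby(labels):
            ax.scatter(sub.iloc[:, i], sub.iloc[:, j], s=12, alpha=0.6, label=str(lab))
        ax.legend(title="group", fontsize=8)
    else:
        ax.scatter(scores.iloc[:, i], scores.iloc[:, j], s=12, alpha=0.6)
    span = float(np.abs(scores.iloc[:, [i, j]].to_numpy()).max())
    for var, row in pca_result.loadings.iterrows():
        fam = str(var).replace("Yr_", "").split("_")[0]
        ax.annotate(
            "", xy=(row.iloc[i] * span, row.iloc[j] * span), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color=_TRAIT_COLORS.get(fam, "gray")),
        )
        ax.text(row.iloc[i] * span * 1.05, row.iloc[j] * span * 1.05, str(var), fontsize=7)
    ev = pca_result.explained_percent
    ax.set_xlabel(f"PC{i + 1} ({ev[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({ev[j]:.1f}%)")
    fig.tight_layout()
    return fig


def yr_trajectory_plot(trajectory: pd.DataFrame, drought_window=None, cut_doys=()):
    """Mean Yr against DOY per variable, drought window shaded, cuts dashed."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for var, sub in trajectory.groupby("variable"):
        sub = sub.sort_values("doy")
        ax.plot(sub["doy"], sub["mean_yr"], marker="o",
                color=_TRAIT_COLORS.get(var, None), label=var)
    if drought_window:
        ax.axvspan(*drought_window, color="orange", alpha=0.15)
    for c in cut_doys:
        ax.axvline(c, ls="--", color="gray", lw=0.8)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("day of year")
    ax.set_ylabel("mean Yr")
    ax.legend()
    fig.tight_layout()
    return fig


def trait_histograms(table: pd.DataFrame, variable: str, bins: int = 30):
    """Per-DOY histograms of one variable (visual bimodality inspection)."""
    sub = table[(table["variable"] == variable) & (table["flag"] == "ok")]
    doys = sorted(sub["doy"].unique())
    fig, axes = plt.subplots(1, max(len(doys), 1), figsize=(3 * max(len(doys), 1), 3), squeeze=False)
    for ax, doy in zip(axes[0], doys):
        for field, fsub in sub[sub["doy"] == doy].groupby("field"):
            ax.hist(fsub["value"], bins=bins, alpha=0.5, label=field)
        ax.set_title(f"{variable}_{doy}", fontsize=9)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    return fig
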