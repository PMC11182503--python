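"""Plots derived strictly from written CSV artifacts.

Every plotting function takes CSV paths produced by the study drivers (not
in-memory objects), so graphical output is reproducible — and testable —
from the tabular artifacts alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_scores",
    "plot_loadings",
    "plot_correlation_loadings",
    "plot_group_derivatives",
]


def plot_scores(
    scores_csv: str | Path,
    out_png: str | Path,
    color_by: str = "genus",
    marker_by: str | None = None,
    title: str = "",
) -> Path:
    """PC1/PC2 score plot colored by a metadata column."""
    df = pd.read_csv(scores_csv)
    fig, ax = plt.subplots(figsize=(7, 6))
    markers = "osv^D*Ph"
    marker_levels = (
        sorted(df[marker_by].astype(str).unique()) if marker_by else [None]
    )
    color_levels = sorted(df[color_by].astype(str).unique())
    cmap = plt.get_cmap("tab20")
    colors = {lvl: cmap(i % 20) for i, lvl in enumerate(color_levels)}
    for ci, clevel in enumerate(color_levels):
        sub = df[df[color_by].astype(str) == clevel]
        for mi, mlevel in enumerate(marker_levels):
            ss = sub if mlevel is None else sub[
                sub[marker_by].astype(str) == mlevel
            ]
            if ss.empty:
                continue
            ax.scatter(
                ss["PC1"], ss["PC2"], s=28, color=colors[clevel],
                marker=markers[mi % len(markers)],
                label=clevel if mi == 0 else None, alpha=0.85,
                edgecolors="none",
            )
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=2, frameon=False)
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_loadings(
    loadings_csv: str | Path, out_png: str | Path, title: str = ""
) -> Path:
    """PC1/PC2 loading line plot against wavenumber."""
    df = pd.read_csv(loadings_csv)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(df["wavenumber"], df["PC1"], color="tab:red", lw=0.9, label="PC1")
    ax.plot(df["wavenumber"], df["PC2"], color="tab:blue", lw=0.9, label="PC2")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.invert_xaxis()  # spectroscopic convention: high wavenumber left
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("loading")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_correlation_loadings(
    corr_csv: str | Path,
    out_png: str | Path,
    moderate: float = 0.5,
    title: str = "",
) -> Path:
    """Correlation-loading plot with the 0.5 (red) and 1.0 (blue) circles."""
    df = pd.read_csv(corr_csv)
    fig, ax = plt.subplots(figsize=(6.5, 6.5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="tab:blue", lw=1.0)
    ax.plot(moderate * np.cos(theta), moderate * np.sin(theta),
            color="tab:red", lw=1.0)
    spectral = df[~df["is_design"]]
    design = df[df["is_design"]]
    ax.scatter(spectral["r1"], spectral["r2"], s=18, color="tab:green",
               label="spectral variables")
    for _, row in spectral.iterrows():
        ax.annotate(str(row["variable"]), (row["r1"], row["r2"]),
                    fontsize=6, alpha=0.7)
    if not design.empty:
        ax.scatter(design["r1"], design["r2"], s=30, color="tab:red",
                   marker="s", label="design variables")
        for _, row in design.iterrows():
            ax.annotate(str(row["variable"]), (row["r1"], row["r2"]),
                        fontsize=7, color="tab:red")
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.set_xlabel("correlation with PC1")
    ax.set_ylabel("correlation with PC2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False, loc="lower right")
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_group_derivatives(
    derivatives_csv: str | Path,
    out_png: str | Path,
    peaks_csv: str | Path | None = None,
    title: str = "",
) -> Path:
    """Annotated group-mean second-derivative spectra.

    ``derivatives_csv``: columns wavenumber then one column per group;
    optional ``peaks_csv`` with columns group, position for annotations.
    """
    df = pd.read_csv(derivatives_csv)
    peaks = pd.read_csv(peaks_csv) if peaks_csv else None
    fig, ax = plt.subplots(figsize=(9, 4.5))
    groups = [col for col in df.columns if col != "wavenumber"]
    cmap = {g: c for g, c in zip(groups, ("tab:red", "tab:blue", "tab:green",
                                          "tab:orange"))}
    for g in groups:
        ax.plot(df["wavenumber"], df[g], lw=0.9,
                color=cmap.get(g, "0.4"), label=g)
        if peaks is not None:
            for pos in peaks.loc[peaks["group"] == g, "position"]:
                ax.axvline(pos, color=cmap.get(g, "0.4"), lw=0.4, alpha=0.35)
    ax.invert_xaxis()
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("2nd derivative (A·cm$^2$)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
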