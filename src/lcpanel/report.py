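"""Simple figures summarizing a pipeline run directory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_formats import read_table

__all__ = ["manhattan", "fst_windows_plot", "assignment_curve_plot",
           "pca_plot", "make_report"]


def _genome_x(df):
    """Cumulative x coordinate and per-chromosome tick positions."""
    x = np.empty(len(df), dtype=float)
    ticks, labels = [], []
    offset = 0.0
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos" if "pos" in grp else "midpoint"].to_numpy(dtype=float)
        x[grp.index] = pos + offset
        ticks.append(offset + pos.mean())
        labels.append(str(chrom))
        offset += pos.max()
    return x, ticks, labels


def manhattan(scan_df, ax=None, threshold=None):
    """-log10(p) per site along the genome."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    x, ticks, labels = _genome_x(scan_df.reset_index(drop=True))
    logp = -np.log10(np.maximum(scan_df["p"].to_numpy(), 1e-300))
    colors = np.array(["#33507a", "#7a9cc6"])
    chrom_idx = scan_df["chrom"].astype("category").cat.codes.to_numpy()
    ax.scatter(x, logp, s=4, c=colors[chrom_idx % 2])
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8)
    ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax


def fst_windows_plot(windows_df, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    x, ticks, labels = _genome_x(windows_df.reset_index(drop=True))
    ax.plot(x, windows_df["fst"].to_numpy(), ".", ms=2, color="#33507a")
    ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
    ax.set_ylabel(r"window $F_{ST}$")
    return ax


def assignment_curve_plot(curves: dict, ax=None):
    """Mean assignment rate vs panel size, one line per selection method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve["panel_size"], curve["mean_rate"], marker="o", ms=3,
                label=name)
    ax.set_xlabel("panel size (loci)")
    ax.set_ylabel("mean assignment rate (K = 2..10)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def pca_plot(pca_df, groups, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for g in np.unique(groups):
        m = groups == g
        ax.scatter(pca_df["PC1"][m], pca_df["PC2"][m], s=12, label=str(g))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    return ax


def make_report(rundir) -> list:
    """Render whichever plots the run directory has inputs for."""
    rundir = Path(rundir)
    written = []

    def save(ax, name):
        ax.figure.tight_layout()
        out = rundir / name
        ax.figure.savefig(out, dpi=120)
        plt.close(ax.figure)
        written.append(out)

    scan = rundir / "scan.tsv"
    if scan.exists():
        df = read_table(scan)
        save(manhattan(df, threshold=0.05 / max(len(df), 1)), "scan.png")
    windows = rundir / "fst_windows.tsv"
    if windows.exists():
        save(fst_windows_plot(read_table(windows)), "fst_windows.png")
    pca = rundir / "pca.tsv"
    pheno = rundir / "phenotypes.tsv"
    if pca.exists() and pheno.exists():
        groups = read_table(pheno)["group"].to_numpy()
        save(pca_plot(read_table(pca), groups), "pca.png")
    curves = {}
    for name in ("grrf", "fst"):
        path = rundir / f"assign_{name}_curve.tsv"
        if path.exists():
            curves[name] = read_table(path)
    if curves:
        save(assignment_curve_plot(curves), "assignment.png")
    return written
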