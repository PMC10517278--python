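"""Rendering of already-computed coupling results (no statistics here)."""

from __future__ import annotations

from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import CouplingResults


def plot_bias(
    results: CouplingResults,
    path: str | Path,
    xlim: float = 2.5,
    ylim: float = 2.5,
    residual: float = 0.5,
    show_genes: bool = False,
) -> Path:
    """Transcriptome-wide expected vs observed 5'-3' isoform frequencies.

    Each point is one (TSS, TES) pair of a tested gene, on log10 frequency
    scales; pairs passing both the significance and residual cutoffs are
    highlighted.  ``xlim``/``ylim`` bound the magnitude of the log10 axes.
    """
    pairs = results.pairs
    if pairs.empty:
        raise ValueError("no pair records to plot")
    totals = pairs.groupby("gene_id")["observed_count"].transform("sum")
    with np.errstate(divide="ignore"):
        obs = np.log10(pairs.observed_count / totals)
        exp = np.log10(pairs.expected_count / totals)
    coupled = pairs.coupled & (pairs.residual.abs() >= residual)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(exp[~coupled], obs[~coupled], s=8, c="0.6", label="not coupled")
    if coupled.any():
        ax.scatter(exp[coupled], obs[coupled], s=12, c="crimson", label="coupled")
        if show_genes:
            for _, row in pairs[coupled].iterrows():
                t = totals[row.name]
                ax.annotate(
                    row.gene_id,
                    (np.log10(row.expected_count / t + 1e-12),
                     np.log10(row.observed_count / t + 1e-12)),
                    fontsize=6,
                )
    lim = [(-xlim, 0), (-ylim, 0)]
    ax.set_xlim(*lim[0])
    ax.set_ylim(*lim[1])
    ax.plot([-max(xlim, ylim), 0], [-max(xlim, ylim), 0], lw=0.5, c="k", ls="--")
    ax.set_xlabel("log10 expected frequency")
    ax.set_ylabel("log10 observed frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_gene(results: CouplingResults, gene_id: str, path: str | Path) -> Path:
    """Stacked per-TES bars of TSS contribution fractions for one gene."""
    dom = results.dominance
    sub = dom[dom.gene_id == gene_id]
    if sub.empty:
        raise KeyError(f"gene {gene_id} not found in dominance records")
    pivot = sub.pivot(index="tes_id", columns="tss_id", values="fraction").fillna(0)
    fig, ax = plt.subplots(figsize=(4, 4))
    bottom = np.zeros(len(pivot))
    for tss in pivot.columns:
        ax.bar(pivot.index, pivot[tss], bottom=bottom, label=tss)
        bottom += pivot[tss].to_numpy()
    ax.set_ylabel("TSS contribution fraction")
    ax.set_title(gene_id)
    ax.legend(frameon=False, fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_exon_couplings(
    results: pd.DataFrame, gene_id: str, path: str | Path, axis: str = "TSS"
) -> Path:
    """Per-junction inclusion residuals by cluster for one gene (one axis)."""
    from .junctions import residual_frame

    sub = results[(results.gene_id == gene_id) & (results.axis == axis)]
    if sub.empty:
        raise KeyError(f"gene {gene_id} / axis {axis} not found in results")
    res = residual_frame(sub)
    fig, ax = plt.subplots(figsize=(6, 4))
    if not res.empty:
        labels = res.junction_start.astype(str) + "-" + res.junction_end.astype(str)
        for cid, grp in res.assign(label=labels).groupby("cluster_id"):
            ax.scatter(grp.label, grp.residual, label=cid, s=20)
        ax.axhline(0, lw=0.5, c="k")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("junction")
    ax.set_ylabel(f"inclusion Pearson residual ({axis})")
    ax.set_title(gene_id)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
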