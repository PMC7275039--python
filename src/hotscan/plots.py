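"""Descriptive figures: Manhattan plot, feature-importance barplot, lollipop."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import MutationCatalog, RegionSet, SNV


def plot_manhattan(calls, mask: RegionSet, fdr_threshold: float, path) -> None:
    """-log10(p) against genomic coordinate; significant calls highlighted."""
    fig, ax = plt.subplots(figsize=(9, 3))
    contigs = mask.contigs
    offsets = {}
    off = 0
    for contig in contigs:
        starts, ends = mask.arrays(contig)
        offsets[contig] = off
        off += int(ends[-1]) if len(ends) else 0
    sig_x, sig_y, bg_x, bg_y = [], [], [], []
    for c in calls:
        x = offsets.get(c.contig, 0) + c.center
        y = -np.log10(max(c.pvalue, 1e-300))
        if c.fdr < fdr_threshold:
            sig_x.append(x)
            sig_y.append(y)
        else:
            bg_x.append(x)
            bg_y.append(y)
    ax.scatter(bg_x, bg_y, s=8, c="grey", label="not significant")
    ax.scatter(sig_x, sig_y, s=14, c="magenta", label=f"FDR < {fdr_threshold}")
    for contig in contigs[1:]:
        ax.axvline(offsets[contig], lw=0.5, c="lightgrey")
    ax.set_xlabel("genomic coordinate")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_xlim(0, max(off, 1))
    if sig_x or bg_x:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_importance(ztable: pd.DataFrame, path) -> None:
    """Horizontal barplot of feature Z-values, largest |Z| on top."""
    if len(ztable) == 0:
        raise ValueError("no features to plot (empty Z-value table)")
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(ztable) + 1.2))
    ordered = ztable.iloc[::-1]
    ax.barh(ordered["feature"], ordered["zvalue"], color="steelblue")
    ax.axvline(0, c="black", lw=0.8)
    ax.set_xlabel("Z-value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lollipop(
    call, catalog: MutationCatalog, flank: int = 50, path=None,
    variant_class: str = SNV,
) -> None:
    """Stem plot of mutated-sample counts per position around one hotspot."""
    lo = call.start - flank
    hi = call.end + flank
    counts: dict[int, set] = {}
    for rec in catalog.records:
        p = rec.position - 1
        if rec.contig == call.contig and lo <= p < hi and rec.variant_class == variant_class:
            counts.setdefault(p, set()).add(rec.sample_id)
    fig, ax = plt.subplots(figsize=(7, 2.5))
    if counts:
        xs = sorted(counts)
        ys = [len(counts[x]) for x in xs]
        ax.stem(xs, ys, basefmt=" ")
    ax.axvspan(call.start, call.end - 1, color="mistyrose", zorder=0)
    ax.set_xlim(lo, hi)
    ax.set_ylim(bottom=0)
    ax.set_xlabel(f"{call.contig} position")
    ax.set_ylabel("mutated samples")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
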