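"""Static genome / chromosome views: log2 ratios, segment bars, AI markers."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

_CATEGORY_COLORS = {
    "conserved_het": "0.6",
    "copy_loss": "tab:green",
    "copy_neutral_loh": "tab:purple",
    "gain_1": "tab:blue",
    "gain_2plus": "tab:red",
}


def plot_genome(results, path=None):
    """One panel of per-exon log2 ratios over all chromosomes."""
    df = results.paired_table[~results.paired_table["excluded"]]
    fig, ax = plt.subplots(figsize=(12, 3.5))
    offset = 0
    ticks, labels = [], []
    for chrom, cdf in df.groupby("chrom", sort=False):
        x = np.arange(len(cdf)) + offset
        ax.plot(x, cdf["log2_ratio"], ".", ms=1.5)
        ticks.append(offset + len(cdf) / 2)
        labels.append(str(chrom))
        offset += len(cdf)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel("log2 case/control ratio")
    ax.set_ylim(-2.5, 2.5)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_chromosome(results, chrom: str, path=None):
    """Per-exon log2 ratios with segment bars and AI markers for one
    chromosome."""
    df = results.paired_table
    cdf = df[(df["chrom"].astype(str) == str(chrom)) & ~df["excluded"]]
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.plot(cdf["start"], cdf["log2_ratio"], ".", ms=2, color="0.4")
    for seg in results.segments:
        if str(seg.chrom) != str(chrom):
            continue
        color = "tab:red" if seg.direction == "gain" else "tab:green"
        ax.hlines(seg.mean_log2, seg.start, seg.end, color=color, lw=4)
    for call in results.ai_calls:
        if str(call.chrom) != str(chrom):
            continue
        ax.plot(call.pos, 2.2, marker="v", ms=4,
                color=_CATEGORY_COLORS.get(call.category, "k"),
                clip_on=False)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel(f"chromosome {chrom} position (bp)")
    ax.set_ylabel("log2 case/control ratio")
    ax.set_ylim(-2.5, 2.5)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
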