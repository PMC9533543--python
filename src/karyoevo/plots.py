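"""Lightweight figures: collinearity dot plots and karyotype ideograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .aek import Painting
from .synteny import CollinearBlock, GeneOrderTable

__all__ = ["dotplot", "painting_ideogram"]


def dotplot(
    blocks: list[CollinearBlock],
    table_a: GeneOrderTable,
    table_b: GeneOrderTable,
    path,
) -> None:
    """Anchor dot plot with cumulative gene-order coordinates."""
    off_a, off_b = {}, {}
    tot = 0
    for chrom in table_a.chrom_names():
        off_a[chrom] = tot
        tot += table_a.chrom_size(chrom)
    tot_a = tot
    tot = 0
    for chrom in table_b.chrom_names():
        off_b[chrom] = tot
        tot += table_b.chrom_size(chrom)
    fig, ax = plt.subplots(figsize=(6, 6))
    for blk in blocks:
        xs = [off_a[blk.chrom_a] + ia for ia, _, _, _ in blk.anchors]
        ys = [off_b[blk.chrom_b] + ib for _, ib, _, _ in blk.anchors]
        ax.plot(xs, ys, ".", ms=1)
    for v in off_a.values():
        ax.axvline(v, color="0.85", lw=0.5)
    for v in off_b.values():
        ax.axhline(v, color="0.85", lw=0.5)
    ax.set_xlim(0, tot_a)
    ax.set_ylim(0, tot)
    ax.set_xlabel(table_a.species_id)
    ax.set_ylabel(table_b.species_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def painting_ideogram(painting: Painting, path) -> None:
    """Chromosomes as horizontal bars coloured by ancestral chromosome."""
    cmap = plt.get_cmap("tab10")
    df = painting.df
    chroms = list(dict.fromkeys(df["chrom"]))
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(chroms) + 1))
    for y, chrom in enumerate(chroms):
        sub = df[df["chrom"] == chrom]
        for row in sub.itertuples():
            color = "0.8" if row.aek_chrom is None or row.aek_chrom != row.aek_chrom else None
            if color is None:
                try:
                    color = cmap((int(row.aek_chrom) - 1) % 10)
                except (TypeError, ValueError):
                    color = "0.8"
            ax.barh(y, 1, left=row.order_index, height=0.8, color=color, lw=0)
        ax.text(-2, y, chrom, ha="right", va="center", fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("gene order index")
    ax.set_title(painting.species_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
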