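#!/usr/bin/env python
"""Collinearity matrix and chromosome clustering.

Detects collinear blocks within and between all simulated genomes, assembles
the collinearity-ratio matrix x_ij = 2*CN_ij/(N_i+N_j), Z-transforms it
row-wise, clusters all chromosomes (average linkage, silhouette-selected k),
and computes pairwise syntenic depth ratios.  Expected outcome under the
simulated conditions: seven clusters, matching the ancestral karyotype.
"""

from pathlib import Path

import pandas as pd

from karyoevo.io import write_blocks
from karyoevo.synteny import (
    GeneOrderTable,
    build_collinearity_matrix,
    cluster_chromosomes,
    detect_blocks,
    syntenic_depth,
    z_normalize,
)

SIM = Path("results/simulated")
OUT = Path("results/synteny")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = [
        GeneOrderTable.read_tsv(p) for p in sorted(SIM.glob("*.gene_order.tsv"))
    ]
    blocks = []
    for i, ta in enumerate(tables):
        for tb in tables[i:]:
            blocks.extend(detect_blocks(ta, tb, min_anchors=5, max_gap=25))
    write_blocks(blocks, OUT / "blocks.tsv")
    print(f"{len(blocks)} collinear blocks across {len(tables)} genomes")

    matrix = z_normalize(build_collinearity_matrix(tables, blocks))
    matrix.x.to_csv(OUT / "collinearity_ratio.tsv", sep="\t")
    matrix.zx.to_csv(OUT / "collinearity_z.tsv", sep="\t")

    clusters = cluster_chromosomes(matrix, k="auto")
    clusters.labels.rename("cluster").to_csv(OUT / "chromosome_clusters.tsv", sep="\t")
    sil = ", ".join(f"k={k}: {v:.3f}" for k, v in sorted(clusters.silhouette_by_k.items()))
    print(f"silhouette scan: {sil}")
    print(f"selected k = {clusters.k} chromosome clusters")

    rows = []
    for i, ta in enumerate(tables):
        for tb in tables[i + 1 :]:
            pair_blocks = [
                b
                for b in blocks
                if {b.species_a, b.species_b} == {ta.species_id, tb.species_id}
            ]
            da, db = syntenic_depth(pair_blocks, ta, tb, window=20)
            rows.append((ta.species_id, tb.species_id, da, db))
            print(f"  depth {ta.species_id}:{tb.species_id} = {da}:{db}")
    pd.DataFrame(rows, columns=["species_a", "species_b", "depth_a", "depth_b"]).to_csv(
        OUT / "syntenic_depths.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
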