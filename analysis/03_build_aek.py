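#!/usr/bin/env python
"""Reconstruct the ancestral karyotype and project it onto every genome.

Per cluster the most collinear chromosome becomes the reference and is
augmented with donor-specific genes (at most five intervening genes between
adjacent anchors of a single block).  Each genome is then painted with the
reconstructed ancestral chromosomes and its copies are ranked by
completeness (A, B, C, ...).  Accuracy is scored against the simulator's
ground-truth ancestry labels.
"""

from pathlib import Path

import pandas as pd

from karyoevo.aek import build_aek, label_copies, project
from karyoevo.io import read_blocks
from karyoevo.scenarios import moderate_dataset
from karyoevo.synteny import GeneOrderTable

SIM = Path("results/simulated")
SYN = Path("results/synteny")
OUT = Path("results/aek")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = [GeneOrderTable.read_tsv(p) for p in sorted(SIM.glob("*.gene_order.tsv"))]
    blocks = read_blocks(SYN / "blocks.tsv")
    result = build_aek(tables, blocks, k="auto")

    rows = []
    for aek in result.aeks:
        for i, fam in enumerate(aek.families):
            sp, chrom, idx = aek.provenance.get(fam, ("?", "?", -1))
            rows.append((aek.aek_id, i, fam, sp, chrom, idx))
    pd.DataFrame(
        rows, columns=["aek_chrom", "aek_index", "family_id", "src_species", "src_chrom", "src_index"]
    ).to_csv(OUT / "aek.tsv", sep="\t", index=False)
    print(
        f"reconstructed {len(result.aeks)} ancestral chromosomes "
        f"(sizes {[len(a) for a in result.aeks]}), references: "
        f"{sorted(result.references.values())}"
    )

    # score against ground truth
    dataset = moderate_dataset(seed=SEED)
    true_chrom = {
        g.family_id: int(c.name.removeprefix("chr"))
        for c in dataset.ancestor.chromosomes
        for g in c.genes
    }
    ancestor_families = set(true_chrom)
    aek_families = set().union(*(set(a.families) for a in result.aeks))
    recall = len(aek_families & ancestor_families) / len(ancestor_families)
    print(f"ancestral family recall: {recall:.3f}")

    lengths = {a.aek_id: len(a) for a in result.aeks}
    aek_to_true = {
        a.aek_id: pd.Series([true_chrom[f] for f in a.families if f in true_chrom]).mode()[0]
        for a in result.aeks
    }
    n_ok = n_tot = 0
    for table in tables:
        gene_truth = {
            g.gene_id: g.true_aek_chrom
            for c in dataset.tips[table.species_id].chromosomes
            for g in c.genes
        }
        painting = project(result.aeks, table)
        labelled = label_copies(painting, lengths)
        labelled.painting.df.to_csv(
            OUT / f"{table.species_id}.painting.tsv", sep="\t", index=False
        )
        sub = painting.df[painting.df["aek_chrom"].notna()]
        ok = sum(
            aek_to_true[int(r.aek_chrom)] == gene_truth[r.gene_id]
            for r in sub.itertuples()
        )
        copies = {
            aek: "".join(lab for lab, _ in labs) for aek, labs in labelled.copies.items()
        }
        print(
            f"  {table.species_id}: painted {len(sub)}/{len(painting.df)} genes, "
            f"ancestry accuracy {ok / len(sub):.3f}, copies per ancestral "
            f"chromosome {copies}"
        )
        n_ok += ok
        n_tot += len(sub)
    print(f"overall painting ancestry accuracy: {n_ok / n_tot:.4f}")


if __name__ == "__main__":
    main()
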