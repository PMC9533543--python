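#!/usr/bin/env python
"""Simulate the six-genome study dataset.

Six species descend from a seven-chromosome, 850-family ancestor; every
lineage carries one whole-genome duplication or triplication (duplicate
retention 0.7) plus a few fusions and bounded inversions.  Writes the
per-species gene-order tables, the ground-truth event log, and the species
tree under results/simulated/.
"""

from pathlib import Path

from karyoevo.io import write_event_log
from karyoevo.scenarios import SIX_SPECIES_TREE, moderate_dataset, tables_from

SEED = 1
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = moderate_dataset(seed=SEED)
    for table in tables_from(dataset):
        table.to_tsv(OUT / f"{table.species_id}.gene_order.tsv")
    write_event_log(dataset.event_log, OUT / "event_log.json")
    (OUT / "species_tree.nwk").write_text(SIX_SPECIES_TREE + "\n")

    print(f"seed {SEED}; ancestor: 7 chromosomes, {dataset.ancestor.n_genes} families")
    for species, genome in sorted(dataset.tips.items()):
        events = [
            e.kind
            for label in dataset.tip_paths[species]
            for e in dataset.event_log.get(label, [])
        ]
        print(
            f"  {species}: {genome.n_chromosomes} chromosomes, "
            f"{genome.n_genes} genes; events: {', '.join(events)}"
        )
    print(f"wrote gene orders, event log and tree to {OUT}/")


if __name__ == "__main__":
    main()
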