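#!/usr/bin/env python
"""Classify chromosome fusions and test whether fusions are shared.

Paintings are condensed to segment strings; EEJ / RTA / NCF calls are made
from the segment patterns and compared with the simulator's ground-truth
event log.  For every pair of species fusing the same ancestral chromosome
pair, the collinearity-continuity test decides shared (inherited) versus
independent (parallel) origin.
"""

import itertools
from pathlib import Path

import pandas as pd

from karyoevo.aek import build_aek, label_copies, project
from karyoevo.fusions import classify_fusion, segment_painting, shared_fusion_test
from karyoevo.io import read_blocks
from karyoevo.scenarios import moderate_dataset
from karyoevo.synteny import GeneOrderTable

SIM = Path("results/simulated")
SYN = Path("results/synteny")
OUT = Path("results/fusions")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = {
        t.species_id: t
        for t in (GeneOrderTable.read_tsv(p) for p in sorted(SIM.glob("*.gene_order.tsv")))
    }
    blocks = read_blocks(SYN / "blocks.tsv")
    result = build_aek(list(tables.values()), blocks, k="auto")
    lengths = {a.aek_id: len(a) for a in result.aeks}

    dataset = moderate_dataset(seed=SEED)
    truth = {
        sp: [e.kind for label in dataset.tip_paths[sp] for e in dataset.event_log.get(label, []) if e.kind in ("EEJ", "RTA", "NCF")]
        for sp in tables
    }

    calls_by_species = {}
    rows = []
    for species, table in sorted(tables.items()):
        painting = label_copies(project(result.aeks, table), lengths).painting
        segments = segment_painting(painting)
        calls = classify_fusion(segments, lengths, species=species)
        calls_by_species[species] = calls
        kinds = [c.kind for c in calls if c.kind != "UNCLASSIFIED"]
        print(f"  {species}: called {kinds or 'none'}; simulated {truth[species] or 'none'}")
        for c in calls:
            rows.append(
                (
                    species, c.kind,
                    ";".join(f"{a}{copy}" for a, copy in c.participants),
                    ";".join(c.chroms),
                    ";".join(f"{j.chrom}@{j.pos:g}" for j in c.junctions),
                )
            )
    pd.DataFrame(
        rows, columns=["species", "kind", "participants", "chromosomes", "junctions"]
    ).to_csv(OUT / "fusion_calls.tsv", sep="\t", index=False)

    comparisons = []
    for sa, sb in itertools.combinations(sorted(tables), 2):
        pair_blocks = [
            b for b in blocks if {b.species_a, b.species_b} == {sa, sb}
        ]
        for fa in calls_by_species[sa]:
            for fb in calls_by_species[sb]:
                if fa.kind == "UNCLASSIFIED" or fb.kind == "UNCLASSIFIED":
                    continue
                if fa.aek_pair != fb.aek_pair:
                    continue
                verdict = shared_fusion_test(fa, fb, pair_blocks)
                comparisons.append(
                    (sa, fa.kind, sb, fb.kind, sorted(fa.aek_pair), verdict)
                )
                print(
                    f"  {sa} {fa.kind} vs {sb} {fb.kind} on ancestral pair "
                    f"{sorted(fa.aek_pair)}: {verdict}"
                )
    if comparisons:
        pd.DataFrame(
            comparisons,
            columns=["species_a", "kind_a", "species_b", "kind_b", "aek_pair", "verdict"],
        ).to_csv(OUT / "shared_fusion_tests.tsv", sep="\t", index=False)
    else:
        print("  no two species fused the same ancestral pair in this replicate")


if __name__ == "__main__":
    main()
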