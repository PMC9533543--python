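"""Declared study scenarios: the fixed simulation conditions the analysis
and the test suite run under.

The *moderate scenario* emulates the six-genome design the reconstruction
pipeline targets: six species descending from a seven-chromosome ancestor
(chromosome sizes 160..90 genes, 850 families), each lineage carrying one
whole-genome duplication or triplication (duplicate retention 0.7 by
default), up to two fusions drawn from the EEJ/RTA/NCF taxonomy, and one or
two inversions.  Chromosome choices and breakpoints are drawn from the
scenario seed; everything else is fixed here so results are reproducible and
comparable across analyses.
"""

from __future__ import annotations

from .clade import SimulatedDataset, simulate_clade
from .genome import simulate_ancestor
from .synteny import CollinearBlock, GeneOrderTable, detect_blocks

__all__ = [
    "SIX_SPECIES_TREE",
    "ANCESTOR_CHROM_SIZES",
    "moderate_scenario",
    "moderate_dataset",
    "tables_from",
    "all_blocks",
]

SIX_SPECIES_TREE = (
    "(((S1:1,S2:1)n12:1,S3:2)n123:1,((S4:1,S5:1)n45:1,S6:2)n456:1)root;"
)

#: Unequal sizes make fusion products dominated by one ancestral chromosome,
#: as in real karyotypes.
ANCESTOR_CHROM_SIZES = (160, 140, 130, 120, 110, 100, 90)


def moderate_scenario(retention: float = 0.7) -> dict[str, list[dict]]:
    """One polyploidy per lineage plus a few rearrangements; random choices
    (which chromosomes, breakpoints) resolve from the dataset seed."""
    return {
        "S1": [
            {"kind": "WGD", "retention": retention},
            {"kind": "EEJ"},
            {"kind": "INVERSION", "max_frac": 0.25},
        ],
        "S2": [
            {"kind": "WGD", "retention": retention},
            {"kind": "RTA"},
        ],
        "S3": [
            {"kind": "WGT", "retention": retention},
            {"kind": "NCF"},
            {"kind": "INVERSION", "max_frac": 0.25},
        ],
        "S4": [
            {"kind": "WGD", "retention": retention},
            {"kind": "EEJ"},
        ],
        "S5": [
            {"kind": "WGD", "retention": retention},
            {"kind": "INVERSION", "max_frac": 0.25},
            {"kind": "INVERSION", "max_frac": 0.25},
        ],
        "S6": [
            {"kind": "WGD", "retention": retention},
            {"kind": "RTA"},
            {"kind": "INVERSION", "max_frac": 0.25},
        ],
    }


def moderate_dataset(seed: int, retention: float = 0.7) -> SimulatedDataset:
    ancestor = simulate_ancestor(7, ANCESTOR_CHROM_SIZES)
    return simulate_clade(
        SIX_SPECIES_TREE, moderate_scenario(retention), seed=seed, ancestor=ancestor
    )


def tables_from(dataset: SimulatedDataset) -> list[GeneOrderTable]:
    return [GeneOrderTable.from_genome(g) for _, g in sorted(dataset.tips.items())]


def all_blocks(
    tables: list[GeneOrderTable], min_anchors: int = 5, max_gap: int = 25
) -> list[CollinearBlock]:
    """Collinear blocks for every genome pair and every self-comparison."""
    blocks: list[CollinearBlock] = []
    for i, ta in enumerate(tables):
        for tb in tables[i:]:
            blocks.extend(detect_blocks(ta, tb, min_anchors=min_anchors, max_gap=max_gap))
    return blocks
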