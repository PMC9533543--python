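"""Ancestral-karyotype reconstruction and projection onto extant genomes.

The pipeline follows the cluster -> reference -> augmentation scheme: all
chromosomes of all species are clustered on the symmetrised Z-transformed
collinearity matrix; within each cluster the member with the highest mean
collinearity ratio to the others becomes the reference; the reference is then
augmented with genes from the other members — whenever a donor carries at
most five genes between two anchors adjacent in a single collinear block,
those genes are inserted between the corresponding reference anchors.  The
augmented references are the ancestral chromosomes.

Projection paints every extant gene with the ancestral chromosome and
position its best anchor maps to (with gap-tolerant in-fill between agreeing
flanks), and copy labelling ranks the multiple post-polyploidy copies of each
ancestral chromosome by completeness: A, B, C, ...
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .synteny import (
    ClusterResult,
    CollinearBlock,
    CollinearityMatrix,
    GeneOrderTable,
    build_collinearity_matrix,
    cluster_chromosomes,
    detect_blocks,
    z_normalize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AEKChromosome",
    "AEKBuildResult",
    "Painting",
    "CopyLabeling",
    "select_reference",
    "augment_reference",
    "build_aek",
    "aek_table",
    "project",
    "label_copies",
]


@dataclass
class AEKChromosome:
    """One reconstructed ancestral chromosome: ordered families with
    provenance (which species/chromosome/position each entry came from)."""

    aek_id: int
    families: list[str]
    provenance: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.families)


def _split_key(key: str) -> tuple[str, str]:
    species, chrom = key.split(":", 1)
    return species, chrom


def select_reference(cluster: list[str], matrix: CollinearityMatrix) -> str:
    """The cluster member with the highest mean collinearity ratio to the
    other members; ties broken by larger gene count, then lexicographic id."""
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        return cluster[0]

    def sort_key(member: str):
        others = [c for c in cluster if c != member]
        mean_x = float(matrix.x.loc[member, others].mean())
        return (-mean_x, -int(matrix.n[member]), member)

    return min(cluster, key=sort_key)


def _chrom_families(table: GeneOrderTable, chrom: str) -> list[str]:
    sub = table.df[table.df["chrom"] == chrom].sort_values("order_index")
    return sub["family_id"].tolist()


def augment_reference(
    ref_key: str,
    donors: list[str],
    blocks: list[CollinearBlock],
    tables: dict[str, GeneOrderTable],
    matrix: CollinearityMatrix,
    max_intervening: int = 5,
    aek_id: int = 0,
) -> AEKChromosome:
    """Insert donor-specific genes into the reference chromosome.

    Donors are processed in decreasing mean collinearity ratio to the
    reference, so the most reliable donor wins family collisions.  For each
    pair of anchors adjacent within one block, donor genes strictly between
    them (1..max_intervening of them) whose families are not yet present are
    inserted between the two reference anchors, preserving donor order
    (reversed for orientation -1 blocks).  Crossing anchor pairs are skipped
    and logged, never fatal.
    """
    ref_species, ref_chrom = _split_key(ref_key)
    ref_fams_all = _chrom_families(tables[ref_species], ref_chrom)
    order: list[str] = []
    prov: dict[str, tuple[str, str, int]] = {}
    for i, fam in enumerate(ref_fams_all):
        if fam not in prov:
            order.append(fam)
            prov[fam] = (ref_species, ref_chrom, i)
    pos = {f: i for i, f in enumerate(order)}

    def reindex() -> None:
        pos.clear()
        pos.update({f: i for i, f in enumerate(order)})

    donors_sorted = sorted(
        donors, key=lambda d: (-float(matrix.x.loc[ref_key, d]), d)
    )
    for donor_key in donors_sorted:
        d_species, d_chrom = _split_key(donor_key)
        d_fams = _chrom_families(tables[d_species], d_chrom)
        for blk in blocks:
            ka = f"{blk.species_a}:{blk.chrom_a}"
            kb = f"{blk.species_b}:{blk.chrom_b}"
            if {ka, kb} != {ref_key, donor_key}:
                continue
            ref_is_a = ka == ref_key
            # anchors as (ref_index, donor_index), ordered along the reference
            anchors = [
                ((ia, ib) if ref_is_a else (ib, ia)) for ia, ib, _, _ in blk.anchors
            ]
            anchors.sort(key=lambda t: t[0])
            for (r0, d0), (r1, d1) in zip(anchors, anchors[1:]):
                lo, hi = (d0, d1) if d0 < d1 else (d1, d0)
                between = list(range(lo + 1, hi))
                if not 1 <= len(between) <= max_intervening:
                    continue
                if d1 < d0:  # orientation -1 run: flip into reference direction
                    between = between[::-1]
                left_fam = ref_fams_all[r0]
                right_fam = ref_fams_all[r1]
                if left_fam not in pos or right_fam not in pos:
                    continue
                if pos[right_fam] <= pos[left_fam]:
                    logger.debug(
                        "skipping crossing insert between %s and %s on %s",
                        left_fam, right_fam, ref_key,
                    )
                    continue
                insert_at = pos[left_fam] + 1
                inserted = False
                for di in between:
                    fam = d_fams[di]
                    if fam in pos:
                        continue
                    order.insert(insert_at, fam)
                    prov[fam] = (d_species, d_chrom, di)
                    insert_at += 1
                    inserted = True
                if inserted:
                    reindex()
    return AEKChromosome(aek_id=aek_id, families=order, provenance=prov)


@dataclass
class AEKBuildResult:
    aeks: list[AEKChromosome]
    clusters: ClusterResult
    matrix: CollinearityMatrix
    references: dict[int, str]  # aek_id -> reference chromosome key


def build_aek(
    tables: list[GeneOrderTable],
    blocks: list[CollinearBlock],
    k: int | str = "auto",
    k_max: int = 12,
    max_intervening: int = 5,
) -> AEKBuildResult:
    """Full reconstruction: cluster chromosomes, pick a reference per
    cluster, augment it, and number the ancestral chromosomes by descending
    family count."""
    if len(tables) < 2:
        raise ValueError("need at least two genomes")
    matrix = z_normalize(build_collinearity_matrix(tables, blocks))
    clusters = cluster_chromosomes(matrix, k=k, k_max=k_max)
    tables_by_species = {t.species_id: t for t in tables}
    built: list[tuple[AEKChromosome, str]] = []
    for label in sorted(set(clusters.labels)):
        members = list(clusters.labels.index[clusters.labels == label])
        ref = select_reference(members, matrix)
        donors = [m for m in members if m != ref]
        aek = augment_reference(
            ref, donors, blocks, tables_by_species, matrix, max_intervening=max_intervening
        )
        built.append((aek, ref))
    built.sort(key=lambda t: (-len(t[0]), t[1]))
    aeks = []
    refs = {}
    for i, (aek, ref) in enumerate(built, start=1):
        aek.aek_id = i
        aeks.append(aek)
        refs[i] = ref
    return AEKBuildResult(aeks=aeks, clusters=clusters, matrix=matrix, references=refs)


def aek_table(aeks: list[AEKChromosome]) -> GeneOrderTable:
    """The ancestral karyotype as a pseudo-genome gene-order table (gene ids
    are family ids), ready for block detection against extant genomes."""
    rows = []
    for aek in aeks:
        for i, fam in enumerate(aek.families):
            rows.append((f"AEK{aek.aek_id}", i, fam, fam, "+"))
    return GeneOrderTable("AEK", pd.DataFrame(rows, columns=GeneOrderTable.COLUMNS))


# ----------------------------------------------------------------------
# projection


@dataclass
class Painting:
    """Per-gene ancestral assignment for one species.

    ``df`` columns: chrom, order_index, gene_id, family_id, aek_chrom
    (nullable int), aek_index (float; fractional for in-filled genes), copy
    (string label, filled by :func:`label_copies`).
    """

    species_id: str
    df: pd.DataFrame

    def assigned_fraction(self) -> float:
        return float(self.df["aek_chrom"].notna().mean())


def project(
    aeks: list[AEKChromosome],
    table: GeneOrderTable,
    blocks: Optional[list[CollinearBlock]] = None,
    min_anchors: int = 5,
    max_gap: int = 25,
    gap_tolerance: int = 10,
) -> Painting:
    """Paint a genome with the ancestral karyotype.

    Anchored genes take the coordinates of their best block (score, then
    lower ancestral chromosome and index); unanchored genes flanked within
    ``gap_tolerance`` genes on both sides by anchors of the same ancestral
    chromosome inherit it with a linearly interpolated index.
    """
    atab = aek_table(aeks)
    if blocks is None:
        target = table
        if table.species_id == "AEK":
            # self-projection: keep the comparison cross-species so the
            # trivial diagonal exclusion does not strip identity anchors
            target = GeneOrderTable("AEK-target", table.df)
        blocks = detect_blocks(atab, target, min_anchors=min_anchors, max_gap=max_gap)
    df = table.df.sort_values(["chrom", "order_index"]).reset_index(drop=True)
    df = df.copy()
    df["aek_chrom"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["aek_index"] = np.nan
    df["copy"] = pd.array([pd.NA] * len(df), dtype="string")
    if not blocks:
        logger.warning("no blocks between AEK and %s: painting left unassigned", table.species_id)
        return Painting(table.species_id, df)

    best: dict[str, tuple] = {}  # gene_id -> (score, -aek_chrom... ) choose max
    for blk in blocks:
        # AEK is always species 'AEK'; figure out which side it is on.
        aek_is_a = blk.species_a == "AEK"
        for ia, ib, ga, gb in blk.anchors:
            if aek_is_a:
                aek_chrom = int(blk.chrom_a.removeprefix("AEK"))
                aek_idx, gene = ia, gb
            else:
                aek_chrom = int(blk.chrom_b.removeprefix("AEK"))
                aek_idx, gene = ib, ga
            cand = (blk.score, -aek_chrom, -aek_idx)
            if gene not in best or cand > best[gene][0]:
                best[gene] = (cand, aek_chrom, aek_idx)
    idx_of = {g: i for i, g in enumerate(df["gene_id"])}
    for gene, (_, ac, ai) in best.items():
        i = idx_of[gene]
        df.loc[i, "aek_chrom"] = ac
        df.loc[i, "aek_index"] = float(ai)

    # gap-tolerant in-fill between agreeing flanks
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        ac = sub["aek_chrom"].to_numpy()
        ai = sub["aek_index"].to_numpy(dtype=float)
        assigned = np.flatnonzero(pd.notna(ac))
        if len(assigned) < 2:
            continue
        for a0, a1 in zip(assigned, assigned[1:]):
            gap = a1 - a0 - 1
            if gap == 0 or gap > gap_tolerance:
                continue
            if ac[a0] != ac[a1]:
                continue
            for p in range(a0 + 1, a1):
                frac = (p - a0) / (a1 - a0)
                df.loc[idx[p], "aek_chrom"] = ac[a0]
                df.loc[idx[p], "aek_index"] = ai[a0] + frac * (ai[a1] - ai[a0])
    return Painting(table.species_id, df)


# ----------------------------------------------------------------------
# copy labelling


@dataclass
class Segment:
    chrom: str
    start: int  # target order_index of first assigned gene
    end: int  # target order_index of last assigned gene
    aek_chrom: int
    families: set  # rounded ancestral indices covered
    row_ids: list[int]  # painting df row positions

    @property
    def size(self) -> int:
        return len(self.row_ids)


@dataclass
class CopyLabeling:
    """Copies of each ancestral chromosome in one genome, ranked by
    completeness (fraction of ancestral families covered): A, B, C, ..."""

    copies: dict[int, list[tuple[str, float]]]  # aek_chrom -> [(label, completeness)]
    painting: Painting

    def completeness(self, aek_chrom: int, label: str) -> float:
        for lab, comp in self.copies.get(aek_chrom, []):
            if lab == label:
                return comp
        raise KeyError((aek_chrom, label))


def _copy_label(i: int) -> str:
    letters = string.ascii_uppercase
    if i < len(letters):
        return letters[i]
    return letters[i % 26] + str(i // 26)


def _paint_segments(df: pd.DataFrame) -> list[Segment]:
    segments: list[Segment] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        current: Optional[Segment] = None
        for row in sub.itertuples():
            if pd.isna(row.aek_chrom):
                continue
            ac = int(row.aek_chrom)
            if current is not None and current.aek_chrom == ac:
                current.end = int(row.order_index)
                current.families.add(int(round(row.aek_index)))
                current.row_ids.append(row.Index)
            else:
                current = Segment(
                    chrom=chrom,
                    start=int(row.order_index),
                    end=int(row.order_index),
                    aek_chrom=ac,
                    families={int(round(row.aek_index))},
                    row_ids=[row.Index],
                )
                segments.append(current)
    return segments


def label_copies(
    painting: Painting,
    aek_lengths: dict[int, int],
    overlap_threshold: float = 0.2,
) -> CopyLabeling:
    """Group painted segments into chromosome copies and rank them.

    Greedy grouping: start a new copy from the largest unused segment; add
    unused segments whose covered ancestral positions overlap the copy's by
    less than ``overlap_threshold`` of their own extent.  Copies are ranked
    by completeness (ties by target chromosome id, then position) and
    labelled alphabetically.
    """
    df = painting.df
    segments = _paint_segments(df)
    copies_out: dict[int, list[tuple[str, float]]] = {}
    for aek_chrom in sorted({s.aek_chrom for s in segments}):
        segs = [s for s in segments if s.aek_chrom == aek_chrom]
        segs.sort(key=lambda s: (-s.size, s.chrom, s.start))
        unused = list(segs)
        groups: list[list[Segment]] = []
        while unused:
            seed_seg = unused.pop(0)
            covered = set(seed_seg.families)
            group = [seed_seg]
            rest = []
            for s in unused:
                if len(s.families & covered) / len(s.families) < overlap_threshold:
                    group.append(s)
                    covered |= s.families
                else:
                    rest.append(s)
            unused = rest
            groups.append(group)
        total = aek_lengths.get(aek_chrom)
        if not total:
            raise KeyError(f"no length known for ancestral chromosome {aek_chrom}")
        ranked = sorted(
            groups,
            key=lambda g: (
                -len(set().union(*(s.families for s in g))) / total,
                min(s.chrom for s in g),
                min(s.start for s in g),
            ),
        )
        labels = []
        for i, group in enumerate(ranked):
            label = _copy_label(i)
            comp = len(set().union(*(s.families for s in group))) / total
            labels.append((label, comp))
            for s in group:
                df.loc[s.row_ids, "copy"] = label
        copies_out[aek_chrom] = labels
    return CopyLabeling(copies=copies_out, painting=painting)
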