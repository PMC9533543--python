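"""Chromosome-fusion classification from karyotype paintings.

A painted (and copy-labelled) genome is condensed into segment strings —
per derived chromosome, the ordered runs of (ancestral chromosome, copy) —
after smoothing away sub-threshold runs.  Fusion calls are made from the
segment patterns:

* NCF (nested chromosome fusion): X–Y–X with the X pieces jointly covering
  most of X and Y covering most of Y;
* EEJ (end-end joining): X then Y, each nearly complete, joined at
  chromosome termini;
* RTA (reciprocally translocated arms): two derived chromosomes carrying
  complementary pieces of X and of Y.

Whether two species' fusions of the same ancestral pair are shared
(inherited) or independent (parallel) is decided by collinearity continuity:
a single collinear block between the two species must run through both
junctions, and the junction-flanking anchors must map within a few anchored
genes of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .aek import Painting
from .synteny import CollinearBlock

__all__ = [
    "FusionSegment",
    "Junction",
    "FusionCall",
    "segment_painting",
    "classify_fusion",
    "shared_fusion_test",
    "detect_fissions",
]


@dataclass
class FusionSegment:
    chrom: str
    aek_chrom: int
    copy: str
    rows: list[tuple[int, str, float]]  # (target order_index, gene_id, aek_index)

    @property
    def size(self) -> int:
        return len(self.rows)

    @property
    def t_start(self) -> int:
        return self.rows[0][0]

    @property
    def t_end(self) -> int:
        return self.rows[-1][0]

    @property
    def aek_positions(self) -> set[int]:
        return {int(round(r[2])) for r in self.rows}

    @property
    def aek_lo(self) -> int:
        return min(self.aek_positions)

    @property
    def aek_hi(self) -> int:
        return max(self.aek_positions)

    @property
    def orientation(self) -> int:
        first, last = self.rows[0][2], self.rows[-1][2]
        return 1 if last >= first else -1

    @property
    def key(self) -> tuple[int, str]:
        return (self.aek_chrom, self.copy)


def segment_painting(
    painting: Painting, min_seg: int = 10
) -> dict[str, list[FusionSegment]]:
    """Condense a copy-labelled painting into per-chromosome segment strings.

    Runs shorter than ``min_seg`` assigned genes are absorbed into the
    flanking segment when both flanks carry the same (ancestral chromosome,
    copy), otherwise dropped to unassigned.
    """
    if painting.df["aek_chrom"].notna().sum() == 0:
        return {}
    out: dict[str, list[FusionSegment]] = {}
    for chrom, sub in painting.df.groupby("chrom", sort=False):
        runs: list[FusionSegment] = []
        for row in sub.sort_values("order_index").itertuples():
            if pd.isna(row.aek_chrom) or pd.isna(row.copy):
                continue
            key = (int(row.aek_chrom), str(row.copy))
            entry = (int(row.order_index), row.gene_id, float(row.aek_index))
            if runs and runs[-1].key == key:
                runs[-1].rows.append(entry)
            else:
                runs.append(FusionSegment(chrom, key[0], key[1], [entry]))
        # smooth: merge or drop short runs until stable
        changed = True
        while changed:
            changed = False
            for i, run in enumerate(runs):
                if run.size >= min_seg:
                    continue
                prev = runs[i - 1] if i > 0 else None
                nxt = runs[i + 1] if i + 1 < len(runs) else None
                if prev is not None and nxt is not None and prev.key == nxt.key:
                    prev.rows.extend(nxt.rows)  # short middle absorbed by flanks
                    runs = runs[:i] + runs[i + 2 :]
                else:
                    runs = runs[:i] + runs[i + 1 :]
                changed = True
                break
            # merge adjacent same-key runs created by drops
            j = 0
            while j + 1 < len(runs):
                if runs[j].key == runs[j + 1].key:
                    runs[j].rows.extend(runs[j + 1].rows)
                    runs = runs[: j + 1] + runs[j + 2 :]
                    changed = True
                else:
                    j += 1
        if runs:
            out[chrom] = runs
    return out


@dataclass
class Junction:
    chrom: str
    pos: float  # inter-gene position on the derived chromosome
    left_gene: str
    right_gene: str
    left_aek: tuple[int, float]  # (aek_chrom, aek_index) of the left flank
    right_aek: tuple[int, float]


@dataclass
class FusionCall:
    kind: str  # EEJ | RTA | NCF | UNCLASSIFIED
    species: str
    participants: list[tuple[int, str]]  # (aek_chrom, copy)
    chroms: list[str]
    junctions: list[Junction]
    coverage: dict[tuple[int, str], float] = field(default_factory=dict)

    @property
    def aek_pair(self) -> frozenset:
        return frozenset(ac for ac, _ in self.participants)


def _junction(left: FusionSegment, right: FusionSegment) -> Junction:
    lt, lg, la = left.rows[-1]
    rt, rg, ra = right.rows[0]
    return Junction(
        chrom=left.chrom,
        pos=(lt + rt) / 2.0,
        left_gene=lg,
        right_gene=rg,
        left_aek=(left.aek_chrom, la),
        right_aek=(right.aek_chrom, ra),
    )


def _coverage(segs: list[FusionSegment], denominator: set[int] | int) -> float:
    """Fraction of ``denominator`` (a position set, or a chromosome length)
    covered by the segments."""
    covered: set[int] = set()
    for s in segs:
        covered |= s.aek_positions
    if isinstance(denominator, int):
        return len(covered) / denominator
    if not denominator:
        return 0.0
    return len(covered & denominator) / len(denominator)


def _copy_extents(
    segments: dict[str, list[FusionSegment]]
) -> dict[tuple[int, str], set[int]]:
    """Genome-wide ancestral positions held by each (aek_chrom, copy).

    Using the copy's own extent as the coverage denominator makes fusion
    calls robust to fractionation: a whole 70%-retained subgenome copy still
    counts as a complete participant.
    """
    out: dict[tuple[int, str], set[int]] = {}
    for segs in segments.values():
        for s in segs:
            out.setdefault(s.key, set()).update(s.aek_positions)
    return out


def _near_terminus(aek_index: float, aek_len: int, eps: int) -> bool:
    return aek_index <= eps or aek_index >= aek_len - 1 - eps


def classify_fusion(
    segments: dict[str, list[FusionSegment]],
    aek_lengths: dict[int, int],
    species: str = "",
    coverage_tau: float = 0.8,
    end_eps: int = 10,
) -> list[FusionCall]:
    """Call fusions from segment strings (see module docstring for the
    patterns).  Multi-segment chromosomes matching no pattern yield
    UNCLASSIFIED calls carrying their junctions."""
    calls: list[FusionCall] = []
    extents = _copy_extents(segments)
    rta_candidates: list[tuple[str, list[FusionSegment]]] = []
    for chrom, segs in segments.items():
        if len(segs) < 2:
            continue
        kinds = [s.aek_chrom for s in segs]
        if len(segs) == 3 and kinds[0] == kinds[2] != kinds[1]:
            cov_x = _coverage([segs[0], segs[2]], extents[segs[0].key])
            cov_y = _coverage([segs[1]], extents[segs[1].key])
            if cov_x >= coverage_tau and cov_y >= coverage_tau:
                calls.append(
                    FusionCall(
                        kind="NCF",
                        species=species,
                        participants=[segs[0].key, segs[1].key],
                        chroms=[chrom],
                        junctions=[_junction(segs[0], segs[1]), _junction(segs[1], segs[2])],
                        coverage={segs[0].key: cov_x, segs[1].key: cov_y},
                    )
                )
                continue
        if len(segs) == 2 and kinds[0] != kinds[1]:
            x_seg, y_seg = segs
            cov_x = _coverage([x_seg], extents[x_seg.key])
            cov_y = _coverage([y_seg], extents[y_seg.key])
            jx_aek = x_seg.rows[-1][2]
            jy_aek = y_seg.rows[0][2]
            if (
                cov_x >= coverage_tau
                and cov_y >= coverage_tau
                and _near_terminus(jx_aek, aek_lengths[x_seg.aek_chrom], end_eps)
                and _near_terminus(jy_aek, aek_lengths[y_seg.aek_chrom], end_eps)
            ):
                calls.append(
                    FusionCall(
                        kind="EEJ",
                        species=species,
                        participants=[x_seg.key, y_seg.key],
                        chroms=[chrom],
                        junctions=[_junction(x_seg, y_seg)],
                        coverage={x_seg.key: cov_x, y_seg.key: cov_y},
                    )
                )
                continue
            rta_candidates.append((chrom, segs))
            continue
        # anything else on this chromosome is unresolved
        calls.append(
            FusionCall(
                kind="UNCLASSIFIED",
                species=species,
                participants=sorted({s.key for s in segs}),
                chroms=[chrom],
                junctions=[_junction(a, b) for a, b in zip(segs, segs[1:])],
                coverage={
                    key: _coverage([s for s in segs if s.key == key], extents[key])
                    for key in {s.key for s in segs}
                },
            )
        )

    # pair 2-segment chromosomes into RTA calls (exhaustive; genomes are small)
    used: set[int] = set()
    for i in range(len(rta_candidates)):
        if i in used:
            continue
        chrom_i, segs_i = rta_candidates[i]
        pair_i = frozenset(s.aek_chrom for s in segs_i)
        for j in range(i + 1, len(rta_candidates)):
            if j in used:
                continue
            chrom_j, segs_j = rta_candidates[j]
            if frozenset(s.aek_chrom for s in segs_j) != pair_i:
                continue
            ok = True
            coverage: dict[tuple[int, str], float] = {}
            for aek_c in pair_i:
                a = next(s for s in segs_i if s.aek_chrom == aek_c)
                b = next(s for s in segs_j if s.aek_chrom == aek_c)
                overlap = len(a.aek_positions & b.aek_positions)
                union = a.aek_positions | b.aek_positions
                denom = extents[a.key] | extents[b.key]
                if overlap > end_eps or len(union & denom) < coverage_tau * len(denom):
                    ok = False
                    break
                coverage[a.key] = len(union & denom) / len(denom)
            if ok:
                used.update({i, j})
                calls.append(
                    FusionCall(
                        kind="RTA",
                        species=species,
                        participants=sorted({s.key for s in segs_i + segs_j}),
                        chroms=[chrom_i, chrom_j],
                        junctions=[
                            _junction(*segs_i),
                            _junction(*segs_j),
                        ],
                        coverage=coverage,
                    )
                )
                break
    for i, (chrom, segs) in enumerate(rta_candidates):
        if i not in used:
            calls.append(
                FusionCall(
                    kind="UNCLASSIFIED",
                    species=species,
                    participants=[s.key for s in segs],
                    chroms=[chrom],
                    junctions=[_junction(*segs)],
                    coverage={s.key: _coverage([s], extents[s.key]) for s in segs},
                )
            )
    return calls


def detect_fissions(
    segments: dict[str, list[FusionSegment]],
    aek_lengths: dict[int, int],
    coverage_tau: float = 0.8,
) -> list[tuple[int, str, list[str]]]:
    """Report ancestral chromosomes whose single copy appears split across
    derived chromosomes that carry no partner segments (fission pattern)."""
    extents = _copy_extents(segments)
    singles: dict[tuple[int, str], list[FusionSegment]] = {}
    for chrom, segs in segments.items():
        if len(segs) == 1:
            singles.setdefault(segs[0].key, []).append(segs[0])
    out = []
    for key, segs in singles.items():
        if len(segs) >= 2 and _coverage(segs, extents[key]) >= coverage_tau:
            if all(_coverage([s], extents[key]) < coverage_tau for s in segs):
                out.append((key[0], key[1], [s.chrom for s in segs]))
    return out


# ----------------------------------------------------------------------
# shared vs independent fusions


def _junction_spanned(
    fusion_a: "FusionCall",
    fusion_b: "FusionCall",
    blocks: list[CollinearBlock],
    window: int,
) -> bool:
    for ja in fusion_a.junctions:
        matched = False
        for jb in fusion_b.junctions:
            for blk in blocks:
                a_is_a = blk.species_a == fusion_a.species
                chrom_a = blk.chrom_a if a_is_a else blk.chrom_b
                chrom_b = blk.chrom_b if a_is_a else blk.chrom_a
                if chrom_a != ja.chrom or chrom_b != jb.chrom:
                    continue
                pos_a = np.array([(x[0] if a_is_a else x[1]) for x in blk.anchors])
                pos_b = np.array([(x[1] if a_is_a else x[0]) for x in blk.anchors])
                if not (
                    (pos_a < ja.pos).any()
                    and (pos_a > ja.pos).any()
                    and (pos_b < jb.pos).any()
                    and (pos_b > jb.pos).any()
                ):
                    continue
                order = np.argsort(pos_a)
                sa, sb = pos_a[order], pos_b[order]
                # Unique crossing of each junction along the monotone chain.
                k = int(np.searchsorted(sa, ja.pos)) - 1
                if sb[0] < sb[-1]:
                    l = int(np.searchsorted(sb, jb.pos)) - 1
                else:  # orientation -1: B positions descend along the chain
                    l = len(sb) - 1 - int(np.searchsorted(sb[::-1], jb.pos))
                if not (0 <= k < len(sa) - 1 and 0 <= l < len(sb) - 1):
                    continue
                gap_a = sa[k + 1] - sa[k] - 1
                gap_b = abs(sb[l + 1] - sb[l]) - 1
                # Intact collinearity through the fusion point: the chain must
                # cross both junctions tightly and at the same place.
                if gap_a <= window and gap_b <= window and abs(k - l) <= window:
                    matched = True
                    break
            if matched:
                break
        if not matched:
            return False
    return True


def shared_fusion_test(
    fusion_a: FusionCall,
    fusion_b: FusionCall,
    blocks: list[CollinearBlock],
    window: int = 10,
) -> str:
    """Decide whether two species' fusions of the same ancestral chromosome
    pair are 'shared' (inherited, collinearity runs intact through both
    junctions) or 'independent' (parallel, junction positions differ).

    ``blocks`` must be collinear blocks between the two species' gene
    orders.  Symmetric in its two arguments.
    """
    if fusion_a.aek_pair != fusion_b.aek_pair:
        raise ValueError(
            f"fusions involve different ancestral pairs: "
            f"{sorted(fusion_a.aek_pair)} vs {sorted(fusion_b.aek_pair)}"
        )
    if (
        fusion_a.species == fusion_b.species
        and {j.chrom for j in fusion_a.junctions} == {j.chrom for j in fusion_b.junctions}
        and {j.pos for j in fusion_a.junctions} == {j.pos for j in fusion_b.junctions}
    ):
        return "shared"
    if _junction_spanned(fusion_a, fusion_b, blocks, window) and _junction_spanned(
        fusion_b, fusion_a, blocks, window
    ):
        return "shared"
    return "independent"
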