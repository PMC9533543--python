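"""Gene-order genomes and the rearrangement/polyploidy events that act on them.

A genome is an ordered list of chromosomes, each an ordered list of genes.
Genes carry a family label (orthology group), an orientation, and — for
simulated genomes — the true ancestral chromosome and position they descend
from, which downstream reconstruction accuracy is scored against.

Coordinates are 0-based gene-order indices; every interval is half-open
``[i, j)``.  Events are recorded as :class:`EvolutionEvent` objects whose
parameters are fully explicit (stochastic gene loss stores its own seed), so
replaying an event list from the ancestor reproduces a genome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeneRecord",
    "Chromosome",
    "Genome",
    "EvolutionEvent",
    "simulate_ancestor",
    "apply_polyploidy",
    "apply_fusion",
    "apply_inversion",
    "apply_fission",
    "apply_event",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a gene-order genome.

    ``true_aek_chrom``/``true_aek_index`` are the ancestral-karyotype
    coordinates the gene descends from (set by the simulator, ``None`` for
    real data).
    """

    gene_id: str
    family_id: str
    orientation: int = 1
    true_aek_chrom: Optional[int] = None
    true_aek_index: Optional[int] = None

    def flipped(self) -> "GeneRecord":
        return replace(self, orientation=-self.orientation)


@dataclass
class Chromosome:
    name: str
    genes: list[GeneRecord]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Genome:
    species_id: str
    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping ---------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        names: set[str] = set()
        for chrom in self.chromosomes:
            if len(chrom.genes) == 0:
                raise ValueError(f"chromosome {chrom.name!r} is empty")
            if chrom.name in names:
                raise ValueError(f"duplicate chromosome name {chrom.name!r}")
            names.add(chrom.name)
            for g in chrom.genes:
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene id {g.gene_id!r}")
                seen.add(g.gene_id)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome {name!r} in {self.species_id}")

    def families(self) -> set[str]:
        return {g.family_id for c in self.chromosomes for g in c.genes}

    def gene_multiset(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.chromosomes:
            for g in c.genes:
                counts[g.family_id] = counts.get(g.family_id, 0) + 1
        return counts

    def copy(self, species_id: Optional[str] = None) -> "Genome":
        return Genome(
            species_id=species_id or self.species_id,
            chromosomes=[Chromosome(c.name, list(c.genes)) for c in self.chromosomes],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.species_id == other.species_id
            and [(c.name, c.genes) for c in self.chromosomes]
            == [(c.name, c.genes) for c in other.chromosomes]
        )


@dataclass(frozen=True)
class EvolutionEvent:
    """A single recorded genome-evolution event.

    ``kind`` is one of WGD, WGT, EEJ, RTA, NCF, FISSION, INVERSION (LOSS is
    folded into the polyploidy events via their retention parameters).
    ``params`` makes the event fully deterministic to replay; ``age`` is the
    event's age in arbitrary time units, used when emitting Ks values.
    """

    kind: str
    params: dict
    age: float = 0.0


# ----------------------------------------------------------------------
# ancestor


def simulate_ancestor(
    n_chrom: int, genes_per_chrom: int | Sequence[int], seed: int = 0
) -> Genome:
    """Build the ancestral genome: ``n_chrom`` chromosomes of single-copy
    families, every gene on the + strand, true ancestry labels set to its own
    position.

    ``genes_per_chrom`` may be a single int or one length per chromosome
    (unequal chromosome sizes make downstream fusion scenarios more
    realistic).  ``seed`` is accepted for interface uniformity; the ancestor
    is deterministic.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if isinstance(genes_per_chrom, int):
        sizes = [genes_per_chrom] * n_chrom
    else:
        sizes = list(genes_per_chrom)
        if len(sizes) != n_chrom:
            raise ValueError("genes_per_chrom length must equal n_chrom")
    if any(s < 1 for s in sizes):
        raise ValueError("genes_per_chrom must be >= 1")
    chroms = []
    for c, size in enumerate(sizes, start=1):
        genes = [
            GeneRecord(
                gene_id=f"g{c:02d}_{i:04d}",
                family_id=f"F{c:02d}_{i:04d}",
                orientation=1,
                true_aek_chrom=c,
                true_aek_index=i,
            )
            for i in range(size)
        ]
        chroms.append(Chromosome(f"chr{c}", genes))
    return Genome(species_id="ancestor", chromosomes=chroms)


# ----------------------------------------------------------------------
# polyploidy


def _retention_vector(retention, multiplicity: int) -> list[float]:
    if isinstance(retention, (int, float)):
        r = float(retention)
        if not 0.0 <= r <= 1.0:
            raise ValueError("retention must be in [0, 1]")
        return [1.0] + [r] * (multiplicity - 1)
    vec = [float(v) for v in retention]
    if len(vec) != multiplicity:
        raise ValueError("per-copy retention must have `multiplicity` entries")
    if any(not 0.0 <= v <= 1.0 for v in vec):
        raise ValueError("retention must be in [0, 1]")
    return vec


def apply_polyploidy(
    genome: Genome,
    multiplicity: int,
    retention,
    seed: int,
    age: float = 0.0,
) -> tuple[Genome, EvolutionEvent]:
    """Whole-genome duplication (multiplicity 2) or triplication (3).

    Every chromosome gains ``multiplicity - 1`` extra copies.  Fractionation:
    per family, the copy-0 gene is kept (scalar ``retention``) while each
    extra copy survives independently with probability ``retention``.  A
    per-copy retention sequence models subgenome-biased fractionation; at
    least one copy of every family always survives.  Copy ``c`` of gene ``x``
    is renamed ``x.c`` (including ``.0``), so gene ids encode the full copy
    path through successive polyploidies.
    """
    if multiplicity not in (2, 3):
        raise ValueError("multiplicity must be 2 (WGD) or 3 (WGT)")
    rvec = _retention_vector(retention, multiplicity)
    rng = np.random.default_rng(seed)

    # Draw survival per (original gene, copy); guarantee one survivor.
    keep: list[list[np.ndarray]] = []  # per chromosome, per copy: bool mask
    for chrom in genome.chromosomes:
        n = len(chrom.genes)
        draws = np.empty((multiplicity, n), dtype=bool)
        for c in range(multiplicity):
            draws[c] = rng.random(n) < rvec[c]
        dead = ~draws.any(axis=0)
        if dead.any():
            best = int(np.argmax(rvec))
            draws[best, dead] = True
        keep.append([draws[c] for c in range(multiplicity)])

    new_chroms: list[Chromosome] = []
    for c in range(multiplicity):
        for ci, chrom in enumerate(genome.chromosomes):
            genes = [
                replace(g, gene_id=f"{g.gene_id}.{c}")
                for g, k in zip(chrom.genes, keep[ci][c])
                if k
            ]
            if not genes:
                continue  # fully fractionated chromosome copy
            # every copy gets a suffix (like gene ids) so repeated
            # polyploidies can never collide on chromosome names
            new_chroms.append(Chromosome(f"{chrom.name}.{c}", genes))
    event = EvolutionEvent(
        kind="WGD" if multiplicity == 2 else "WGT",
        params={"multiplicity": multiplicity, "retention": rvec, "seed": int(seed)},
        age=age,
    )
    return Genome(genome.species_id, new_chroms), event


# ----------------------------------------------------------------------
# fusions / fissions / inversions


def _take(chrom: Chromosome, i: int, j: int) -> list[GeneRecord]:
    return chrom.genes[i:j]


def _reversed_run(genes: list[GeneRecord]) -> list[GeneRecord]:
    return [g.flipped() for g in reversed(genes)]


def apply_fusion(
    genome: Genome,
    kind: str,
    chroms: tuple[str, str],
    breakpoints: Optional[Sequence[int]] = None,
    age: float = 0.0,
    eej_ends: tuple[str, str] = ("tail", "head"),
) -> tuple[Genome, EvolutionEvent]:
    """Fuse two chromosomes.

    EEJ concatenates whole chromosomes (by default tail of X onto head of Y;
    ``eej_ends`` selects other end combinations, reversing a partner where
    needed).  RTA at interior breakpoints ``(bx, by)`` swaps arms, producing
    ``X[0:bx]+Y[by:]`` and ``Y[0:by]+X[bx:]``.  NCF at interior point ``p``
    nests all of Y inside X: ``X[0:p]+Y+X[p:]``.  Gene content is always
    preserved.
    """
    xname, yname = chroms
    if xname == yname:
        raise ValueError("fusion requires two distinct chromosomes")
    X = genome.chromosome(xname)
    Y = genome.chromosome(yname)
    rest = [c for c in genome.chromosomes if c.name not in (xname, yname)]

    if kind == "EEJ":
        xg = list(X.genes)
        yg = list(Y.genes)
        ex, ey = eej_ends
        if ex == "head":
            xg = _reversed_run(xg)  # join at original head: flip X
        elif ex != "tail":
            raise ValueError("eej_ends[0] must be 'tail' or 'head'")
        if ey == "tail":
            yg = _reversed_run(yg)
        elif ey != "head":
            raise ValueError("eej_ends[1] must be 'head' or 'tail'")
        fused = Chromosome(f"{xname}+{yname}", xg + yg)
        new = rest + [fused]
        params = {"chroms": [xname, yname], "eej_ends": list(eej_ends)}
    elif kind == "RTA":
        if breakpoints is None or len(breakpoints) != 2:
            raise ValueError("RTA needs breakpoints (bx, by)")
        bx, by = breakpoints
        if not (0 < bx < len(X)) or not (0 < by < len(Y)):
            raise ValueError("RTA breakpoints must be interior")
        d1 = Chromosome(f"{xname}x{yname}_1", _take(X, 0, bx) + _take(Y, by, len(Y)))
        d2 = Chromosome(f"{xname}x{yname}_2", _take(Y, 0, by) + _take(X, bx, len(X)))
        new = rest + [d1, d2]
        params = {"chroms": [xname, yname], "breakpoints": [int(bx), int(by)]}
    elif kind == "NCF":
        if breakpoints is None or len(breakpoints) != 1:
            raise ValueError("NCF needs a single insertion point")
        (p,) = breakpoints
        if not (0 < p < len(X)):
            raise ValueError("NCF insertion point must be interior to X")
        fused = Chromosome(
            f"{xname}<{yname}>", _take(X, 0, p) + list(Y.genes) + _take(X, p, len(X))
        )
        new = rest + [fused]
        params = {"chroms": [xname, yname], "breakpoints": [int(p)]}
    else:
        raise ValueError(f"unknown fusion kind {kind!r}")
    event = EvolutionEvent(kind=kind, params=params, age=age)
    return Genome(genome.species_id, new), event


def apply_inversion(
    genome: Genome, chrom: str, i: int, j: int, age: float = 0.0
) -> tuple[Genome, EvolutionEvent]:
    """Reverse segment ``[i, j)`` of a chromosome, flipping orientations."""
    C = genome.chromosome(chrom)
    if not (0 <= i < j <= len(C)):
        raise ValueError(f"invalid inversion interval [{i}, {j}) on {chrom!r}")
    genes = C.genes[:i] + _reversed_run(C.genes[i:j]) + C.genes[j:]
    new = [Chromosome(c.name, genes) if c.name == chrom else c for c in genome.chromosomes]
    event = EvolutionEvent(
        kind="INVERSION", params={"chrom": chrom, "interval": [int(i), int(j)]}, age=age
    )
    return Genome(genome.species_id, new), event


def apply_fission(
    genome: Genome, chrom: str, p: int, age: float = 0.0
) -> tuple[Genome, EvolutionEvent]:
    """Split a chromosome at interior point ``p`` into ``[0, p)`` and ``[p, end)``."""
    C = genome.chromosome(chrom)
    if not (0 < p < len(C)):
        raise ValueError("fission point must be interior")
    a = Chromosome(f"{chrom}a", C.genes[:p])
    b = Chromosome(f"{chrom}b", C.genes[p:])
    new = [c for c in genome.chromosomes if c.name != chrom] + [a, b]
    event = EvolutionEvent(kind="FISSION", params={"chrom": chrom, "point": int(p)}, age=age)
    return Genome(genome.species_id, new), event


# ----------------------------------------------------------------------
# replay


def apply_event(genome: Genome, event: EvolutionEvent) -> Genome:
    """Replay one recorded event; the dispatcher behind event-log replay."""
    k = event.kind
    p = event.params
    if k in ("WGD", "WGT"):
        g, _ = apply_polyploidy(
            genome, p["multiplicity"], p["retention"], p["seed"], age=event.age
        )
    elif k in ("EEJ", "RTA", "NCF"):
        g, _ = apply_fusion(
            genome,
            k,
            tuple(p["chroms"]),
            breakpoints=p.get("breakpoints"),
            age=event.age,
            eej_ends=tuple(p.get("eej_ends", ("tail", "head"))),
        )
    elif k == "INVERSION":
        g, _ = apply_inversion(genome, p["chrom"], *p["interval"], age=event.age)
    elif k == "FISSION":
        g, _ = apply_fission(genome, p["chrom"], p["point"], age=event.age)
    else:
        raise ValueError(f"unknown event kind {k!r}")
    return g
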