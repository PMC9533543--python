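"""Clade-level simulation: evolve an ancestral genome down a species tree.

A *scenario* assigns each species-tree branch (identified by the label of the
node the branch leads to; tips by their taxon label) an ordered list of event
specifications.  Unspecified choices — which chromosomes fuse, where
breakpoints fall — are drawn from a single seeded generator in documented
(preorder, then per-branch) order, then recorded explicitly, so the resulting
event log replays to byte-identical tip genomes without any randomness.

Branch lengths of the input tree are read as ages in arbitrary time units
(the same units event ages use); the tree is assumed ultrametric for age
computation.  Ks emission turns pair divergence ages into lognormal Ks draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .genome import (
    EvolutionEvent,
    Genome,
    apply_event,
    apply_fission,
    apply_fusion,
    apply_inversion,
    apply_polyploidy,
    simulate_ancestor,
)

__all__ = ["SimulatedDataset", "simulate_clade", "replay", "emit_ks"]


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{id(node)}"


def _node_ages(tree: dendropy.Tree) -> dict[str, float]:
    """Age (time before present) per node label, tips at 0."""
    ages: dict[str, float] = {}

    def age_of(node: dendropy.Node) -> float:
        if node.is_leaf():
            a = 0.0
        else:
            a = max(
                age_of(ch) + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
        ages[_node_label(node)] = a
        return a

    age_of(tree.seed_node)
    return ages


@dataclass
class SimulatedDataset:
    """A simulated clade: ancestor, tip genomes, and the ground-truth log."""

    newick: str
    ancestor: Genome
    tips: dict[str, Genome]
    event_log: dict[str, list[EvolutionEvent]]
    tip_paths: dict[str, list[str]]  # root-to-tip branch labels per tip
    node_ages: dict[str, float]

    def polyploidy_events(self, tip: str) -> list[EvolutionEvent]:
        return [
            e
            for label in self.tip_paths[tip]
            for e in self.event_log.get(label, [])
            if e.kind in ("WGD", "WGT")
        ]

    def mrca_age(self, tip_a: str, tip_b: str) -> float:
        pa, pb = self.tip_paths[tip_a], self.tip_paths[tip_b]
        shared = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            shared += 1
        if shared == 0:
            raise ValueError("tips share no path prefix (disconnected tree?)")
        # MRCA is the last shared node on the two root-to-tip paths.
        return self.node_ages[pa[shared - 1]]

    def shared_polyploidy_count(self, tip_a: str, tip_b: str) -> int:
        pa, pb = self.tip_paths[tip_a], self.tip_paths[tip_b]
        n = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            n += len([e for e in self.event_log.get(x, []) if e.kind in ("WGD", "WGT")])
        return n


def _copy_path(gene_id: str) -> tuple[int, ...]:
    """Copy indices appended by successive polyploidies: 'g01_0001.0.2' -> (0, 2)."""
    parts = gene_id.split(".")
    return tuple(int(p) for p in parts[1:])


def _resolve_event(
    spec: dict, genome: Genome, rng: np.random.Generator, age: float
) -> tuple[Genome, EvolutionEvent]:
    kind = spec["kind"].upper()
    age = float(spec.get("age", age))
    if kind in ("WGD", "WGT"):
        mult = 2 if kind == "WGD" else 3
        retention = spec.get("retention", 1.0)
        seed = int(spec.get("seed", rng.integers(0, 2**31 - 1)))
        return apply_polyploidy(genome, mult, retention, seed, age=age)
    names = [c.name for c in genome.chromosomes]
    if kind in ("EEJ", "RTA", "NCF"):
        if "chroms" in spec:
            x, y = spec["chroms"]
        else:
            if len(names) < 2:
                raise ValueError("fusion needs at least two chromosomes")
            x, y = (names[i] for i in rng.choice(len(names), size=2, replace=False))
        if kind == "EEJ":
            return apply_fusion(
                genome, "EEJ", (x, y), age=age,
                eej_ends=tuple(spec.get("eej_ends", ("tail", "head"))),
            )
        if kind == "RTA":
            bps = spec.get("breakpoints")
            if bps is None:
                lx = len(genome.chromosome(x))
                ly = len(genome.chromosome(y))
                bps = (int(rng.integers(1, lx)), int(rng.integers(1, ly)))
            return apply_fusion(genome, "RTA", (x, y), breakpoints=bps, age=age)
        bps = spec.get("breakpoints")
        if bps is None:
            lx = len(genome.chromosome(x))
            bps = (int(rng.integers(1, lx)),)
        return apply_fusion(genome, "NCF", (x, y), breakpoints=bps, age=age)
    if kind == "INVERSION":
        chrom = spec.get("chrom") or names[int(rng.integers(len(names)))]
        if "interval" in spec:
            i, j = spec["interval"]
        else:
            n = len(genome.chromosome(chrom))
            # optional cap on the inverted span (fraction of the chromosome)
            max_len = max(1, int(spec.get("max_frac", 1.0) * n))
            length = int(rng.integers(1, max_len + 1))
            i = int(rng.integers(0, n - length + 1))
            j = i + length
        return apply_inversion(genome, chrom, i, j, age=age)
    if kind == "FISSION":
        chrom = spec.get("chrom") or names[int(rng.integers(len(names)))]
        n = len(genome.chromosome(chrom))
        if n < 2:
            raise ValueError("cannot split a single-gene chromosome")
        p = int(spec.get("point", rng.integers(1, n)))
        return apply_fission(genome, chrom, p, age=age)
    raise ValueError(f"unknown event kind {kind!r}")


def simulate_clade(
    species_tree: str,
    scenario: dict[str, list[dict]],
    seed: int,
    ancestor: Optional[Genome] = None,
    n_chrom: int = 7,
    genes_per_chrom=100,
) -> SimulatedDataset:
    """Evolve the ancestor down ``species_tree`` (newick) under ``scenario``.

    Scenario keys must name tree branches (tip taxa or internal-node labels);
    unknown keys are rejected.  Events within a branch apply oldest-first;
    unspecified ages are spaced evenly along the branch.
    """
    tree = dendropy.Tree.get(data=species_tree, schema="newick")
    ages = _node_ages(tree)
    labels = {_node_label(n) for n in tree.preorder_node_iter()}
    unknown = set(scenario) - labels
    if unknown:
        raise ValueError(f"scenario references unknown branches: {sorted(unknown)}")

    if ancestor is None:
        ancestor = simulate_ancestor(n_chrom, genes_per_chrom)
    rng = np.random.default_rng(seed)

    event_log: dict[str, list[EvolutionEvent]] = {}
    tips: dict[str, Genome] = {}
    tip_paths: dict[str, list[str]] = {}

    def descend(node: dendropy.Node, genome: Genome, path: list[str]) -> None:
        label = _node_label(node)
        path = path + [label]
        specs = scenario.get(label, [])
        if specs:
            log: list[EvolutionEvent] = []
            parent_age = (
                ages[_node_label(node.parent_node)]
                if node.parent_node is not None
                else ages[label] + 1.0
            )
            child_age = ages[label]
            for i, spec in enumerate(specs):
                # Oldest-first default ages, evenly spaced along the branch.
                frac = (i + 1) / (len(specs) + 1)
                default_age = parent_age - frac * (parent_age - child_age)
                genome, ev = _resolve_event(spec, genome, rng, default_age)
                log.append(ev)
            event_log[label] = log
        if node.is_leaf():
            tips[label] = genome.copy(species_id=label)
            tip_paths[label] = path
        else:
            for ch in node.child_nodes():
                descend(ch, genome, path)

    descend(tree.seed_node, ancestor.copy(), [])
    return SimulatedDataset(
        newick=species_tree,
        ancestor=ancestor,
        tips=tips,
        event_log=event_log,
        tip_paths=tip_paths,
        node_ages=ages,
    )


def replay(dataset: SimulatedDataset) -> dict[str, Genome]:
    """Re-derive every tip genome from the ancestor and the event log alone."""
    tree = dendropy.Tree.get(data=dataset.newick, schema="newick")
    tips: dict[str, Genome] = {}

    def descend(node: dendropy.Node, genome: Genome) -> None:
        label = _node_label(node)
        for ev in dataset.event_log.get(label, []):
            genome = apply_event(genome, ev)
        if node.is_leaf():
            tips[label] = genome.copy(species_id=label)
        else:
            for ch in node.child_nodes():
                descend(ch, genome)

    descend(tree.seed_node, dataset.ancestor.copy())
    return tips


# ----------------------------------------------------------------------
# Ks emission


def _pair_age_within(
    dataset: SimulatedDataset, tip: str, id_a: str, id_b: str
) -> float:
    events = dataset.polyploidy_events(tip)
    pa, pb = _copy_path(id_a), _copy_path(id_b)
    for k, (x, y) in enumerate(zip(pa, pb)):
        if x != y:
            return events[k].age
    raise ValueError(f"genes {id_a}/{id_b} share a full copy path")


def _pair_age_between(
    dataset: SimulatedDataset, tip_a: str, id_a: str, tip_b: str, id_b: str
) -> float:
    n_shared = dataset.shared_polyploidy_count(tip_a, tip_b)
    pa, pb = _copy_path(id_a), _copy_path(id_b)
    for k in range(min(n_shared, len(pa), len(pb))):
        if pa[k] != pb[k]:
            ev = dataset.polyploidy_events(tip_a)[k]
            return ev.age
    return dataset.mrca_age(tip_a, tip_b)


def emit_ks(
    dataset: SimulatedDataset,
    ks_per_age: float,
    cv: float,
    seed: int,
    within: Optional[list[str]] = None,
    between: Optional[list[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Draw a Ks value for every same-family gene pair.

    A pair whose lineages diverged at age ``a`` receives a lognormal draw
    with median ``a * ks_per_age`` and coefficient of variation ``cv``
    (``cv=0`` collapses to the exact median).  ``within`` lists species for
    intragenomic paralog pairs (default: all tips); ``between`` lists species
    pairs for ortholog/ohnolog pairs (default: none).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    rows: list[tuple] = []

    def draw(median: float) -> float:
        if median <= 0:
            return 0.0
        if sigma == 0.0:
            return median
        return float(np.exp(np.log(median) + sigma * rng.standard_normal()))

    if within is None:
        within = sorted(dataset.tips)
    for sp in within:
        genome = dataset.tips[sp]
        by_family: dict[str, list[str]] = {}
        for chrom in genome.chromosomes:
            for g in chrom.genes:
                by_family.setdefault(g.family_id, []).append(g.gene_id)
        for fam, ids in by_family.items():
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    age = _pair_age_within(dataset, sp, ids[i], ids[j])
                    rows.append((sp, ids[i], sp, ids[j], fam, age, draw(age * ks_per_age)))

    for sp_a, sp_b in between or []:
        ga, gb = dataset.tips[sp_a], dataset.tips[sp_b]
        fam_b: dict[str, list[str]] = {}
        for chrom in gb.chromosomes:
            for g in chrom.genes:
                fam_b.setdefault(g.family_id, []).append(g.gene_id)
        for chrom in ga.chromosomes:
            for g in chrom.genes:
                for other in fam_b.get(g.family_id, []):
                    age = _pair_age_between(dataset, sp_a, g.gene_id, sp_b, other)
                    rows.append(
                        (sp_a, g.gene_id, sp_b, other, g.family_id, age, draw(age * ks_per_age))
                    )

    return pd.DataFrame(
        rows,
        columns=["species_a", "gene_a", "species_b", "gene_b", "family_id", "age", "ks"],
    )
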