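"""Multispecies-coalescent gene-tree simulation, with optional introgression.

Branch lengths of the species tree are coalescent units (generations scaled
by 2N).  One haploid lineage is sampled per species by default.  Tracing
backward in time, lineages coalesce within each species-tree branch at rate
k(k-1)/2 and surviving lineages move into the parent branch; at the root they
coalesce to a single lineage.  An introgression pulse (donor, recipient,
gamma[, time]) reroutes each lineage present in the recipient branch at the
pulse time into the donor branch with probability gamma.

For a rooted triple with internal branch T the probability that the gene
tree matches the species tree is 1 - (2/3) e^(-T); the simulator is tested
against this closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

__all__ = ["simulate_gene_trees_msc"]


@dataclass
class _Lineage:
    nwk: str  # newick of the subtree below this lineage
    t: float  # age of the subtree root


@dataclass
class _Pop:
    label: str
    lo: float
    hi: float  # math.inf for the root branch
    parent: Optional[str]
    depth: int = 0  # root = 0; deeper populations merge first on time ties


def _build_pops(tree: dendropy.Tree) -> tuple[dict[str, _Pop], dict[str, float]]:
    ages: dict[dendropy.Node, float] = {}

    def age_of(node: dendropy.Node) -> float:
        if node in ages:
            return ages[node]
        if node.is_leaf():
            a = 0.0
        else:
            a = max(age_of(c) + (c.edge.length or 0.0) for c in node.child_nodes())
        ages[node] = a
        return a

    age_of(tree.seed_node)
    pops: dict[str, _Pop] = {}
    node_age: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length in species tree")
        label = node.taxon.label if node.taxon else (node.label or f"n{id(node)}")
        node_age[label] = ages[node]
        depth = sum(1 for _ in node.ancestor_iter())
        if node.parent_node is None:
            pops[label] = _Pop(label, ages[node], math.inf, None, depth)
        else:
            p = node.parent_node
            plabel = p.taxon.label if p.taxon else (p.label or f"n{id(p)}")
            pops[label] = _Pop(label, ages[node], ages[p], plabel, depth)
    return pops, node_age


def _coalesce_segment(
    lineages: list[_Lineage], t0: float, t1: float, rng: np.random.Generator
) -> float:
    """Coalesce in place between times t0 and t1; return the reached time."""
    t = t0
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0
        t_next = t + rng.exponential(1.0 / rate)
        if t_next >= t1:
            return t1
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        merged = _Lineage(
            nwk=f"({a.nwk}:{t_next - a.t:.10g},{b.nwk}:{t_next - b.t:.10g})",
            t=t_next,
        )
        lineages[:] = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        t = t_next
    return t1


def simulate_gene_trees_msc(
    species_tree: str,
    n_trees: int,
    seed: int,
    introgression: Optional[Sequence] = None,
    samples_per_species: int | dict[str, int] = 1,
) -> list[str]:
    """Sample ``n_trees`` rooted gene trees (newick strings, coalescent-unit
    branch lengths) under the MSC on ``species_tree``.

    ``introgression`` is ``(donor, recipient, gamma)`` or
    ``(donor, recipient, gamma, time)``; with the time omitted the pulse is
    placed just above the base of the overlap of the two branches' intervals.
    """
    tree = dendropy.Tree.get(data=species_tree, schema="newick")
    pops, _ = _build_pops(tree)
    tip_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]

    pulse = None
    if introgression is not None:
        if len(introgression) == 3:
            donor, recipient, gamma = introgression
            t_mix = None
        else:
            donor, recipient, gamma, t_mix = introgression
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("introgression proportion must be in [0, 1]")
        for lbl in (donor, recipient):
            if lbl not in pops:
                raise ValueError(f"unknown branch {lbl!r} in introgression spec")
        lo = max(pops[donor].lo, pops[recipient].lo)
        hi = min(pops[donor].hi, pops[recipient].hi)
        if t_mix is None:
            if not math.isfinite(hi):
                hi = lo + 1.0
            if hi <= lo:
                raise ValueError("donor and recipient branches do not overlap in time")
            t_mix = lo + 0.01 * (hi - lo)
        if not (pops[donor].lo <= t_mix < pops[donor].hi) or not (
            pops[recipient].lo <= t_mix < pops[recipient].hi
        ):
            raise ValueError("introgression time outside the two branches")
        pulse = (donor, recipient, float(gamma), float(t_mix))

    if isinstance(samples_per_species, int):
        nsamp = {t: samples_per_species for t in tip_labels}
    else:
        nsamp = {t: samples_per_species.get(t, 1) for t in tip_labels}

    rng = np.random.default_rng(seed)
    # Boundary times: pulse, then each non-root population's end.
    # (time, kind 0=pulse/1=merge, -depth, pop): pulses first on ties, then
    # deeper populations, so children always merge before their parent ends.
    boundaries: list[tuple[float, int, int, str]] = []
    if pulse is not None:
        boundaries.append((pulse[3], 0, -pops[pulse[1]].depth, pulse[1]))
    for p in pops.values():
        if math.isfinite(p.hi):
            boundaries.append((p.hi, 1, -p.depth, p.label))
    boundaries.sort()

    out: list[str] = []
    for _ in range(n_trees):
        active: dict[str, list[_Lineage]] = {p: [] for p in pops}
        clock: dict[str, float] = {p.label: p.lo for p in pops.values()}
        for t in tip_labels:
            if nsamp[t] == 1:
                active[t].append(_Lineage(t, 0.0))
            else:
                for i in range(nsamp[t]):
                    active[t].append(_Lineage(f"{t}|{i + 1}", 0.0))

        for time, kind, _neg_depth, label in boundaries:
            # Advance every population that has pending lineages up to `time`.
            for p in pops.values():
                if clock[p.label] < time <= p.hi and active[p.label]:
                    clock[p.label] = _coalesce_segment(
                        active[p.label], max(clock[p.label], p.lo), time, rng
                    )
                elif clock[p.label] < time <= p.hi:
                    clock[p.label] = time
            if kind == 0 and pulse is not None:
                donor, recipient, gamma, _t = pulse
                stay, move = [], []
                for lin in active[recipient]:
                    (move if rng.random() < gamma else stay).append(lin)
                active[recipient] = stay
                active[donor].extend(move)
            else:
                pop = pops[label]
                active[pop.parent].extend(active[label])
                active[label] = []

        # Root population: coalesce to a single lineage.
        root = next(p for p in pops.values() if p.parent is None)
        lineages = active[root.label]
        t = max(clock[root.label], root.lo)
        while len(lineages) > 1:
            k = len(lineages)
            t = t + rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(
                _Lineage(f"({a.nwk}:{t - a.t:.10g},{b.nwk}:{t - b.t:.10g})", t)
            )
        out.append(lineages[0].nwk + ";")
    return out
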