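"""Decomposing gene-tree/species-tree discordance at each internal node into
gene-tree estimation error, incomplete lineage sorting (ILS), and
hybridization.

Per node the pipeline computes: gene-tree support (percentage of gene trees
containing the node's bipartition); theta = 2m/d, the population-scaled
mutation rate recovered from the branch's length in mutation units (m,
substitutions/site) and coalescent units (d) — high theta marks high-ILS
branches; an estimation-error support (how often the node is recovered from
sequences simulated on the species tree itself, so every failure is
estimation error); and a reticulation index — under pure ILS the two minor
topologies of any rooted triplet around a node are equally frequent, so a
chi-squared excess of one minor topology, calibrated against ILS-only
simulated trees, flags hybridization.  The relative importance of the three
factors for node support is decomposed with the lmg R^2-averaging scheme.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .gtrsim import simulate_sequences_gtr
from .msc import simulate_gene_trees_msc

__all__ = [
    "GeneTreeSet",
    "bipartition_support",
    "estimate_theta",
    "coalescent_units_from_concordance",
    "TripletCounts",
    "triplet_counts",
    "reticulation_index",
    "estimation_error_support",
    "nj_tree",
    "jc_distance",
    "SaturationError",
    "LmgResult",
    "lmg_decomposition",
]


# ----------------------------------------------------------------------
# gene-tree containers


class GeneTreeSet:
    """Parsed gene trees with cached leaf sets and unrooted splits."""

    def __init__(self, newicks: Sequence[str]):
        self.leaf_sets: list[frozenset] = []
        self.splits: list[list[frozenset]] = []
        for nwk in newicks:
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            sp = []
            for node in tree.preorder_internal_node_iter():
                if node.parent_node is None:
                    continue
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                if 0 < len(below) < len(leaves):
                    sp.append(below)
            self.leaf_sets.append(leaves)
            self.splits.append(sp)

    def __len__(self) -> int:
        return len(self.leaf_sets)


def _species_clades(tree: dendropy.Tree) -> dict[str, frozenset]:
    """Label -> leafset for internal non-root nodes of the species tree."""
    out = {}
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        if node.parent_node is None:
            continue
        label = node.label or f"node{i}"
        out[label] = frozenset(l.taxon.label for l in node.leaf_iter())
    return out


def bipartition_support(
    species_tree: str, gene_trees: Sequence[str] | GeneTreeSet
) -> dict[str, float]:
    """Percentage of gene trees whose splits contain each internal
    bipartition of the species tree, restricted to shared taxa; trees
    uninformative for a bipartition are excluded from its denominator."""
    stree = dendropy.Tree.get(data=species_tree, schema="newick")
    taxa = frozenset(l.taxon.label for l in stree.leaf_node_iter())
    gts = gene_trees if isinstance(gene_trees, GeneTreeSet) else GeneTreeSet(gene_trees)
    for leaves in gts.leaf_sets:
        bad = leaves - taxa
        if bad:
            raise ValueError(f"gene-tree leaves not in species tree: {sorted(bad)}")
    support: dict[str, float] = {}
    for label, clade in _species_clades(stree).items():
        n_inf = n_hit = 0
        for leaves, splits in zip(gts.leaf_sets, gts.splits):
            inside = clade & leaves
            outside = leaves - clade
            if len(inside) < 2 or len(outside) < 2:
                continue
            n_inf += 1
            for s in splits:
                if s == inside or leaves - s == inside:
                    n_hit += 1
                    break
        support[label] = 100.0 * n_hit / n_inf if n_inf else float("nan")
    return support


# ----------------------------------------------------------------------
# theta


def estimate_theta(mutation_branch_length: float, coalescent_branch_length: float) -> float:
    """theta = 2m/d: with d = t/2N and m = mu*t, 2m/d = 4*N*mu."""
    if coalescent_branch_length <= 0:
        raise ValueError("coalescent branch length must be positive")
    if mutation_branch_length < 0:
        raise ValueError("mutation branch length must be nonnegative")
    return 2.0 * mutation_branch_length / coalescent_branch_length


def coalescent_units_from_concordance(concordant_fraction: float) -> float:
    """Invert P(concordant) = 1 - (2/3) e^(-T) for the internal branch length
    T in coalescent units."""
    if not 1.0 / 3.0 < concordant_fraction <= 1.0:
        raise ValueError("concordant fraction must be in (1/3, 1]")
    if concordant_fraction == 1.0:
        return float("inf")
    return -math.log(1.5 * (1.0 - concordant_fraction))


# ----------------------------------------------------------------------
# triplets


@dataclass
class TripletCounts:
    taxa: tuple[str, str, str]
    n_major: int  # ((A,B),C): the species-tree resolution for the caller
    n_minor1: int  # ((A,C),B)
    n_minor2: int  # ((B,C),A)
    n_skipped: int

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor1 + self.n_minor2


def _triplet_topology(
    leaves: frozenset, splits: list[frozenset], a: str, b: str, c: str, outgroup: str
) -> Optional[int]:
    """0: ((a,b),c); 1: ((a,c),b); 2: ((b,c),a); None: unresolved."""
    four = {a, b, c, outgroup}
    pairs = [(a, b), (a, c), (b, c)]
    for k, (x, y) in enumerate(pairs):
        pair = {x, y}
        rest = four - pair
        for s in splits:
            side = s & four
            if side == pair or side == rest:
                return k
    return None


def triplet_counts(
    gene_trees: Sequence[str] | GeneTreeSet,
    taxa: tuple[str, str, str],
    outgroup: str,
) -> TripletCounts:
    """Rooted triplet topology counts over gene trees containing all of
    ``taxa`` plus the ``outgroup`` (which roots each tree); trees missing
    any are skipped and tallied."""
    a, b, c = taxa
    gts = gene_trees if isinstance(gene_trees, GeneTreeSet) else GeneTreeSet(gene_trees)
    counts = [0, 0, 0]
    skipped = 0
    needed = {a, b, c, outgroup}
    for leaves, splits in zip(gts.leaf_sets, gts.splits):
        if not needed <= leaves:
            skipped += 1
            continue
        topo = _triplet_topology(leaves, splits, a, b, c, outgroup)
        if topo is None:
            skipped += 1
            continue
        counts[topo] += 1
    return TripletCounts(taxa, counts[0], counts[1], counts[2], skipped)


# ----------------------------------------------------------------------
# reticulation index


def _node_triples(
    stree: dendropy.Tree, outgroup: Optional[str]
) -> dict[str, tuple[list[str], list[str], list[str]]]:
    """Per internal node: taxa of its two child subtrees and of the rest of
    the tree (minus the outgroup), the three pools triplets sample from."""
    all_taxa = {l.taxon.label for l in stree.leaf_node_iter()}
    out = {}
    for i, node in enumerate(stree.preorder_internal_node_iter()):
        if node.parent_node is None:
            continue
        children = node.child_nodes()
        if len(children) != 2:
            continue
        c1 = [l.taxon.label for l in children[0].leaf_iter()]
        c2 = [l.taxon.label for l in children[1].leaf_iter()]
        below = set(c1) | set(c2)
        rest = sorted(all_taxa - below - ({outgroup} if outgroup else set()))
        label = node.label or f"node{i}"
        out[label] = (sorted(c1), sorted(c2), rest)
    return out


def reticulation_index(
    species_tree: str,
    gene_trees: Sequence[str] | GeneTreeSet,
    ils_null_trees: Sequence[str] | GeneTreeSet,
    outgroup: str,
    alpha: float = 0.05,
    max_combos: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-node hybridization signal.

    For every internal node, triplet combinations (one taxon from each child
    subtree, one from outside, capped at ``max_combos``, seeded) are tested:
    the two minor topology counts in the observed trees are compared by
    chi-squared test against the null minor-topology proportions estimated
    from the ILS-only simulated trees (equality, up to sampling), with
    Benjamini-Hochberg correction across combinations.  The reticulation
    index of a node is the rejected fraction; the raw mean minor-topology
    imbalance |m1-m2|/(m1+m2) is reported alongside.
    """
    stree = dendropy.Tree.get(data=species_tree, schema="newick")
    gts = gene_trees if isinstance(gene_trees, GeneTreeSet) else GeneTreeSet(gene_trees)
    nulls = (
        ils_null_trees
        if isinstance(ils_null_trees, GeneTreeSet)
        else GeneTreeSet(ils_null_trees)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for label, (c1, c2, rest) in _node_triples(stree, outgroup).items():
        combos = list(itertools.product(c1, c2, rest))
        if not combos:
            rows.append((label, 0, float("nan"), float("nan")))
            continue
        if len(combos) > max_combos:
            pick = rng.choice(len(combos), size=max_combos, replace=False)
            combos = [combos[i] for i in sorted(pick)]
        pvals = []
        imbalances = []
        for a, b, c in combos:
            obs = triplet_counts(gts, (a, b, c), outgroup)
            null = triplet_counts(nulls, (a, b, c), outgroup)
            m1, m2 = obs.n_minor1, obs.n_minor2
            s1, s2 = null.n_minor1, null.n_minor2
            if m1 + m2 == 0 or s1 + s2 == 0:
                continue
            # two-sample comparison so the null calibration's own sampling
            # noise is respected (the ILS-only minors are symmetric only in
            # expectation)
            table = np.array([[m1, m2], [s1, s2]])
            if (table.sum(axis=0) == 0).any():
                pvals.append(1.0)  # degenerate: same single minor on both sides
            else:
                pvals.append(float(stats.chi2_contingency(table, correction=False).pvalue))
            imbalances.append(abs(m1 - m2) / (m1 + m2))
        if not pvals:
            rows.append((label, 0, float("nan"), float("nan")))
            continue
        rejected = _benjamini_hochberg(np.array(pvals), alpha)
        rows.append(
            (label, len(pvals), float(rejected.mean()), float(np.mean(imbalances)))
        )
    return pd.DataFrame(
        rows, columns=["node", "n_combos", "reticulation_index", "mean_minor_imbalance"]
    )


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean rejection mask at FDR alpha."""
    n = len(pvals)
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresh
    k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
    out = np.zeros(n, dtype=bool)
    out[order[:k]] = True
    return out


# ----------------------------------------------------------------------
# distances and neighbor joining


class SaturationError(ValueError):
    """Observed divergence too high for the distance correction."""


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) for mismatch fraction p,
    with pairwise deletion of gapped sites; saturation (p >= 3/4) raises."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    n = mism = 0
    for x, y in zip(seq_a, seq_b):
        if x == "-" or y == "-":
            continue
        n += 1
        mism += x != y
    if n == 0:
        raise ValueError("no comparable sites")
    p = mism / n
    if p >= 0.75:
        raise SaturationError(f"mismatch fraction {p:.3f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor joining on a symmetric distance matrix (labels from the
    DataFrame index); returns an unrooted newick string.  Additive distances
    are recovered exactly."""
    d = distances.to_numpy(dtype=float)
    labels = list(distances.index)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [f"{lab}" for lab in labels]
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = active[i_], active[j_]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dk])
        d = np.hstack([d, np.append(dk, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        return (
            f"({nodes[i]}:{max(li, 0):.10g},{nodes[j]}:{max(lj, 0):.10g},"
            f"{nodes[k]}:{max(lk, 0):.10g});"
        )
    i, j = active
    return f"({nodes[i]}:{d[i, j] / 2:.10g},{nodes[j]}:{d[i, j] / 2:.10g});"


# ----------------------------------------------------------------------
# estimation error


def estimation_error_support(
    species_tree: str,
    n_sim: int = 200,
    length: int = 1500,
    exchangeabilities: Sequence[float] = (1, 1, 1, 1, 1, 1),
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[dict[str, float], int]:
    """Support attributable to finite data alone.

    ``n_sim`` alignments are simulated on the species tree itself (gene tree
    identical to species tree, so any failure to recover a node is
    estimation error), trees are rebuilt by neighbor joining on JC-corrected
    distances, and the per-node recovery percentage is returned together
    with the number of replicates skipped for saturation.
    """
    stree = dendropy.Tree.get(data=species_tree, schema="newick")
    clades = _species_clades(stree)
    taxa = sorted(l.taxon.label for l in stree.leaf_node_iter())
    full = frozenset(taxa)
    hits = {label: 0 for label in clades}
    n_used = 0
    n_skipped = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_sim):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        seqs = simulate_sequences_gtr(
            species_tree, length, exchangeabilities, base_freqs, seed=rep_seed
        )
        try:
            mat = np.zeros((len(taxa), len(taxa)))
            for x in range(len(taxa)):
                for y in range(x + 1, len(taxa)):
                    mat[x, y] = mat[y, x] = jc_distance(seqs[taxa[x]], seqs[taxa[y]])
        except SaturationError:
            n_skipped += 1
            continue
        nwk = nj_tree(pd.DataFrame(mat, index=taxa, columns=taxa))
        rebuilt = GeneTreeSet([nwk])
        splits = rebuilt.splits[0]
        n_used += 1
        for label, clade in clades.items():
            if len(clade) < 2 or len(full - clade) < 2:
                continue
            if any(s == clade or full - s == clade for s in splits):
                hits[label] += 1
    support = {
        label: (100.0 * h / n_used if n_used else float("nan"))
        for label, h in hits.items()
    }
    return support, n_skipped


# ----------------------------------------------------------------------
# lmg relative importance


@dataclass
class LmgResult:
    shares: pd.Series  # per-predictor importance, summing to the full R^2
    r2: float


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    A = np.hstack([np.ones((n, 1)), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("response has zero variance")
    return 1.0 - (resid**2).sum() / tss


def lmg_decomposition(response, predictors) -> LmgResult:
    """lmg relative-importance decomposition: each predictor's share is the
    average, over all orderings of the predictors, of the R^2 increment it
    contributes when added after its predecessors.  Shares sum to the
    full-model R^2.  Computed via the subset-weight identity rather than
    explicit permutation enumeration."""
    X = (
        predictors.to_numpy(dtype=float)
        if isinstance(predictors, pd.DataFrame)
        else np.asarray(predictors, dtype=float)
    )
    names = (
        list(predictors.columns)
        if isinstance(predictors, pd.DataFrame)
        else [f"x{i}" for i in range(X.shape[1])]
    )
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 observations")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < p:
        raise ValueError("predictors are rank-deficient after centering")
    r2_cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            cols = sorted(subset)
            r2_cache[subset] = _r2(y, X[:, cols]) if cols else 0.0
        return r2_cache[subset]

    shares = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [k for k in others if k != j]
        for size in range(p):
            w = (
                math.factorial(size)
                * math.factorial(p - 1 - size)
                / math.factorial(p)
            )
            for S in itertools.combinations(rest, size):
                s = frozenset(S)
                shares[j] += w * (r2_of(s | {j}) - r2_of(s))
    return LmgResult(shares=pd.Series(shares, index=names), r2=r2_of(frozenset(range(p))))
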