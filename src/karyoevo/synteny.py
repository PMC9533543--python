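"""Collinear-block detection and the collinearity-ratio machinery.

Blocks are maximal monotonic chains of anchors (same-family gene pairs) with
bounded inter-anchor gaps, extracted iteratively by dynamic programming so
that overlapping polyploidy-derived blocks on one chromosome pair are all
retained.  From all retained blocks the per-chromosome-pair collinearity
ratio x_ij = 2*CN_ij / (N_i + N_j) is assembled over every chromosome of
every species, row-normalised by Z-transformation, and clustered
(agglomerative, average linkage) to recover ancestral chromosome groups.
Syntenic depth ratios (e.g. 2:1 after one unshared WGD) are computed from
block coverage of sliding gene windows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .genome import Genome

__all__ = [
    "GeneOrderTable",
    "CollinearBlock",
    "CollinearityMatrix",
    "detect_blocks",
    "collinearity_ratio",
    "build_collinearity_matrix",
    "z_normalize",
    "cluster_chromosomes",
    "ClusterResult",
    "syntenic_depth",
]


# ----------------------------------------------------------------------
# gene-order tables


@dataclass
class GeneOrderTable:
    """Ordered genes of one species: (chrom, order_index, gene_id, family_id, strand)."""

    species_id: str
    df: pd.DataFrame

    COLUMNS = ["chrom", "order_index", "gene_id", "family_id", "strand"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene-order table missing columns {missing}")
        if self.df.empty:
            raise ValueError("empty gene-order table")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in gene-order table")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            idx = np.sort(sub["order_index"].to_numpy())
            if not np.array_equal(idx, np.arange(len(sub))):
                raise ValueError(f"order_index not consecutive from 0 on {chrom!r}")

    @classmethod
    def from_genome(cls, genome: Genome) -> "GeneOrderTable":
        rows = []
        for chrom in genome.chromosomes:
            for i, g in enumerate(chrom.genes):
                rows.append(
                    (chrom.name, i, g.gene_id, g.family_id, "+" if g.orientation > 0 else "-")
                )
        return cls(genome.species_id, pd.DataFrame(rows, columns=cls.COLUMNS))

    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_size(self, chrom: str) -> int:
        return int((self.df["chrom"] == chrom).sum())

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "species", self.species_id)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneOrderTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        species = str(df["species"].iloc[0])
        return cls(species, df[cls.COLUMNS].reset_index(drop=True))


@dataclass
class CollinearBlock:
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    orientation: int  # +1: both ascending; -1: B descending
    anchors: list[tuple[int, int, str, str]]  # (index_a, index_b, gene_a, gene_b)
    block_id: int = -1

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def score(self) -> int:
        return len(self.anchors)

    def span_a(self) -> tuple[int, int]:
        ia = [a[0] for a in self.anchors]
        return min(ia), max(ia)

    def span_b(self) -> tuple[int, int]:
        ib = [a[1] for a in self.anchors]
        return min(ib), max(ib)

    def validate(self, min_anchors: int, max_gap: int) -> None:
        """Independent validity check: monotone, gap-bounded, big enough."""
        if self.n_anchors < min_anchors:
            raise AssertionError("block below min_anchors")
        prev = None
        for ia, ib, _, _ in self.anchors:
            if prev is not None:
                pa, pb = prev
                if not (pa < ia and ia - pa - 1 <= max_gap):
                    raise AssertionError("A-side monotonicity/gap violated")
                if self.orientation > 0:
                    if not (pb < ib and ib - pb - 1 <= max_gap):
                        raise AssertionError("B-side monotonicity/gap violated")
                else:
                    if not (pb > ib and pb - ib - 1 <= max_gap):
                        raise AssertionError("B-side monotonicity/gap violated")
            prev = (ia, ib)


# ----------------------------------------------------------------------
# chaining


def _best_chain(a: np.ndarray, b: np.ndarray, orientation: int, max_gap: int) -> list[int]:
    """Highest-anchor-count monotone chain with bounded gaps (ties: first found).

    Returns indices into ``a``/``b`` in chain order.
    """
    n = len(a)
    if n == 0:
        return []
    order = np.lexsort((b if orientation > 0 else -b, a))
    sa = a[order]
    sb = b[order]
    score = np.ones(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        ok = (sa < sa[i]) & (sa >= sa[i] - max_gap - 1)
        if orientation > 0:
            ok &= (sb < sb[i]) & (sb >= sb[i] - max_gap - 1)
        else:
            ok &= (sb > sb[i]) & (sb <= sb[i] + max_gap + 1)
        if ok.any():
            j = int(np.flatnonzero(ok)[np.argmax(score[np.flatnonzero(ok)])])
            score[i] = score[j] + 1
            parent[i] = j
    end = int(np.argmax(score))
    chain = []
    while end != -1:
        chain.append(int(order[end]))
        end = int(parent[end])
    return chain[::-1]


def _chrom_arrays(table: GeneOrderTable) -> dict[str, tuple[np.ndarray, list, list]]:
    out = {}
    for chrom, sub in table.df.groupby("chrom", sort=False):
        sub = sub.sort_values("order_index")
        out[chrom] = (
            sub["family_id"].to_numpy(),
            sub["gene_id"].tolist(),
            sub["order_index"].to_numpy(),
        )
    return out


def detect_blocks(
    table_a: GeneOrderTable,
    table_b: GeneOrderTable,
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Detect collinear blocks between two gene-order tables (or one table
    against itself; the trivial self-diagonal is excluded).

    Anchors are enumerated for every copy combination of shared families;
    blocks are extracted best-first, removing each block's anchors, until no
    chain of ``min_anchors`` remains — so overlapping WGD-derived blocks on
    the same chromosome pair are all kept.
    """
    self_cmp = table_a.species_id == table_b.species_id
    ca = _chrom_arrays(table_a)
    cb = _chrom_arrays(table_b)
    blocks: list[CollinearBlock] = []
    bid = 0
    chroms_a = list(ca)
    chroms_b = list(cb)
    for xi, chrom_x in enumerate(chroms_a):
        fam_x, genes_x, _ = ca[chrom_x]
        fam_index: dict[str, list[int]] = {}
        for i, f in enumerate(fam_x):
            fam_index.setdefault(f, []).append(i)
        for yi, chrom_y in enumerate(chroms_b):
            if self_cmp and yi < xi:
                continue  # unordered pairs once
            fam_y, genes_y, _ = cb[chrom_y]
            aa, bb = [], []
            for j, f in enumerate(fam_y):
                for i in fam_index.get(f, ()):
                    if self_cmp and chrom_x == chrom_y and i == j:
                        continue  # trivial diagonal
                    aa.append(i)
                    bb.append(j)
            if len(aa) < min_anchors:
                continue
            a = np.asarray(aa)
            b = np.asarray(bb)
            alive = np.ones(len(a), dtype=bool)
            while alive.sum() >= min_anchors:
                idx = np.flatnonzero(alive)
                fwd = _best_chain(a[idx], b[idx], +1, max_gap)
                rev = _best_chain(a[idx], b[idx], -1, max_gap)
                if len(fwd) >= len(rev):
                    chain, orient = fwd, +1
                else:
                    chain, orient = rev, -1
                if len(chain) < min_anchors:
                    break
                chosen = idx[chain]
                anchors = [
                    (int(a[k]), int(b[k]), genes_x[a[k]], genes_y[b[k]]) for k in chosen
                ]
                blocks.append(
                    CollinearBlock(
                        species_a=table_a.species_id,
                        species_b=table_b.species_id,
                        chrom_a=chrom_x,
                        chrom_b=chrom_y,
                        orientation=orient,
                        anchors=anchors,
                        block_id=bid,
                    )
                )
                bid += 1
                alive[chosen] = False
    return blocks


# ----------------------------------------------------------------------
# collinearity matrix


def collinearity_ratio(cn: int, n_i: int, n_j: int) -> float:
    """x_ij = 2*CN_ij / (N_i + N_j), the fraction of the two chromosomes'
    genes lying in shared collinear blocks."""
    if n_i < 1 or n_j < 1:
        raise ValueError("chromosome gene counts must be >= 1")
    if cn < 0 or cn > min(n_i, n_j):
        raise ValueError(f"CN={cn} outside [0, min(N_i, N_j)={min(n_i, n_j)}]")
    return 2.0 * cn / (n_i + n_j)


@dataclass
class CollinearityMatrix:
    """x_ij over all chromosomes of all species (keys 'species:chrom'),
    with anchor counts CN, gene counts N, and optionally the Z-scores."""

    x: pd.DataFrame
    cn: pd.DataFrame
    n: pd.Series
    zx: Optional[pd.DataFrame] = None

    @property
    def keys(self) -> list[str]:
        return list(self.x.index)


def build_collinearity_matrix(
    tables: list[GeneOrderTable], blocks: list[CollinearBlock]
) -> CollinearityMatrix:
    """Assemble x_ij from retained blocks.  CN counts each anchored gene pair
    once (deduplicated across overlapping blocks), making x_ii' = 1 for
    identical chromosomes."""
    keys: list[str] = []
    n: dict[str, int] = {}
    for t in tables:
        for chrom in t.chrom_names():
            key = f"{t.species_id}:{chrom}"
            keys.append(key)
            n[key] = t.chrom_size(chrom)
    pair_sets: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for blk in blocks:
        ka = f"{blk.species_a}:{blk.chrom_a}"
        kb = f"{blk.species_b}:{blk.chrom_b}"
        if ka == kb:
            continue  # self-diagonal handled upstream; intra-chromosome pairs excluded
        key = (ka, kb) if ka <= kb else (kb, ka)
        s = pair_sets.setdefault(key, set())
        for ia, ib, ga, gb in blk.anchors:
            s.add((ga, gb) if ka <= kb else (gb, ga))
    x = pd.DataFrame(0.0, index=keys, columns=keys)
    cn = pd.DataFrame(0, index=keys, columns=keys)
    for (ka, kb), pairs in pair_sets.items():
        c = len(pairs)
        cn.loc[ka, kb] = cn.loc[kb, ka] = c
        val = collinearity_ratio(min(c, min(n[ka], n[kb])), n[ka], n[kb])
        x.loc[ka, kb] = x.loc[kb, ka] = val
    return CollinearityMatrix(x=x, cn=cn, n=pd.Series(n))


def z_normalize(matrix: CollinearityMatrix) -> CollinearityMatrix:
    """Row-wise Z-transformation Zx_ij = (x_ij - mu_i) / sigma_i, with mu_i
    and sigma_i (sample sd) over row i excluding the diagonal."""
    x = matrix.x
    vals = x.to_numpy(dtype=float).copy()
    k = len(vals)
    z = np.zeros_like(vals)
    for i in range(k):
        row = np.delete(vals[i], i)
        mu = row.mean()
        sd = row.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"degenerate row (sigma=0) for chromosome {x.index[i]!r}")
        z[i] = (vals[i] - mu) / sd
        z[i, i] = 0.0
    return CollinearityMatrix(
        x=matrix.x, cn=matrix.cn, n=matrix.n, zx=pd.DataFrame(z, index=x.index, columns=x.columns)
    )


@dataclass
class ClusterResult:
    labels: pd.Series  # cluster label per chromosome key
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def cluster_chromosomes(
    matrix: CollinearityMatrix, k: int | str = "auto", k_max: int = 12
) -> ClusterResult:
    """Group chromosomes into ancestral clusters.

    Distance d_ij = max(S) - S_ij with S the symmetrised Z matrix;
    agglomerative clustering with average linkage.  With ``k='auto'`` the
    cluster count maximising the mean silhouette over k in [2, k_max] is
    selected.
    """
    if matrix.zx is None:
        matrix = z_normalize(matrix)
    z = matrix.zx.to_numpy(dtype=float)
    s = (z + z.T) / 2.0
    d = s.max() - s
    np.fill_diagonal(d, 0.0)
    n = len(d)
    if isinstance(k, int):
        if k > n:
            raise ValueError(f"k={k} exceeds number of chromosomes ({n})")
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
        labels = model.fit_predict(d)
        return ClusterResult(labels=pd.Series(labels, index=matrix.zx.index), k=k)
    sil: dict[int, float] = {}
    best_k, best_labels, best_s = None, None, -np.inf
    for kk in range(2, min(k_max, n - 1) + 1):
        model = AgglomerativeClustering(n_clusters=kk, metric="precomputed", linkage="average")
        labels = model.fit_predict(d)
        sc = silhouette_score(d, labels, metric="precomputed")
        sil[kk] = float(sc)
        if sc > best_s:
            best_k, best_labels, best_s = kk, labels, sc
    return ClusterResult(
        labels=pd.Series(best_labels, index=matrix.zx.index), k=int(best_k), silhouette_by_k=sil
    )


# ----------------------------------------------------------------------
# syntenic depth


def _modal_cover(
    blocks: list[CollinearBlock],
    table: GeneOrderTable,
    side: str,
    window: int,
) -> int:
    """Modal number of distinct partner blocks fully covering tiled windows
    of ``window`` consecutive genes of ``table`` (windows with >= 1 cover)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for blk in blocks:
        chrom = blk.chrom_b if side == "b" else blk.chrom_a
        span = blk.span_b() if side == "b" else blk.span_a()
        spans.setdefault(chrom, []).append(span)
    counts: Counter = Counter()
    for chrom in table.chrom_names():
        size = table.chrom_size(chrom)
        ch_spans = spans.get(chrom, [])
        for w0 in range(0, size - window + 1, window):
            w1 = w0 + window - 1
            c = sum(1 for lo, hi in ch_spans if lo <= w0 and hi >= w1)
            if c >= 1:
                counts[c] += 1
    if not counts:
        raise ValueError("no covered windows: syntenic depth undefined")
    return max(counts, key=lambda c: (counts[c], -c))


def syntenic_depth(
    blocks: list[CollinearBlock],
    table_a: GeneOrderTable,
    table_b: GeneOrderTable,
    window: int = 20,
) -> tuple[int, int]:
    """Modal syntenic depths (A over B, B over A) from blocks between the two
    genomes; e.g. (2, 1) when A carries an unshared WGD."""
    if not blocks:
        raise ValueError("no blocks: syntenic depth undefined")
    return (
        _modal_cover(blocks, table_b, "b", window),
        _modal_cover(blocks, table_a, "a", window),
    )
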