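"""Polyploidy inference: block-level Ks summaries, mixture peak fitting, and
the collinear-gene-tree monophyly test for shared vs independent
whole-genome duplications.

Ks (synonymous substitutions per synonymous site) distributions of syntenic
blocks peak at polyploidy events; each block is summarised by its median Ks
and peaks are found by Gaussian-mixture fitting on log Ks with BIC model
selection.  Independence of WGDs in two species P and Q is judged per
collinear gene tree: root the tree on a random copy from one species — if
the other species' copies form a monophyletic clade, the duplication
post-dates the P/Q split, supporting independent WGDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .synteny import CollinearBlock

__all__ = [
    "block_median_ks",
    "KsPeakModel",
    "fit_ks_peaks",
    "WGDTreeTestResult",
    "collinear_tree_wgd_test",
]


def block_median_ks(
    blocks: list[CollinearBlock], ks: pd.DataFrame
) -> pd.DataFrame:
    """Median Ks per collinear block (exact median; NaNs skipped; blocks with
    no valid Ks omitted).

    ``ks`` needs columns gene_a, gene_b, ks; pairs are matched to anchors
    irrespective of order.
    """
    lookup: dict[frozenset, float] = {}
    for row in ks.itertuples():
        lookup[frozenset((row.gene_a, row.gene_b))] = row.ks
    rows = []
    for blk in blocks:
        vals = []
        for _, _, ga, gb in blk.anchors:
            v = lookup.get(frozenset((ga, gb)))
            if v is not None and np.isfinite(v):
                vals.append(v)
        if not vals:
            continue
        rows.append(
            (
                blk.block_id,
                f"{blk.species_a}:{blk.chrom_a}",
                f"{blk.species_b}:{blk.chrom_b}",
                len(vals),
                float(np.median(vals)),
            )
        )
    return pd.DataFrame(
        rows, columns=["block_id", "chrom_a", "chrom_b", "n_ks", "median_ks"]
    )


@dataclass
class KsPeakModel:
    """Gaussian mixture on log Ks: per component (weight, log-mean, log-sd),
    the BIC-selected component count, and peak modes on the Ks scale."""

    weights: np.ndarray
    log_means: np.ndarray
    log_sds: np.ndarray
    n_components: int
    bic: dict[int, float]

    @property
    def modes(self) -> np.ndarray:
        return np.sort(np.exp(self.log_means))


def fit_ks_peaks(
    medians: Sequence[float],
    max_components: int = 4,
    ks_window: tuple[float, float] = (0.01, 3.0),
    seed: int = 0,
    min_points: int = 20,
) -> KsPeakModel:
    """Fit 1..max_components Gaussian mixtures to log(median Ks) inside
    ``ks_window``; the component count minimising BIC wins."""
    vals = np.asarray(medians, dtype=float)
    vals = vals[np.isfinite(vals) & (vals >= ks_window[0]) & (vals <= ks_window[1])]
    if len(vals) < min_points:
        raise ValueError(
            f"only {len(vals)} Ks medians inside {ks_window}; need >= {min_points}"
        )
    logv = np.log(vals).reshape(-1, 1)
    bics: dict[int, float] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, n_init=5, random_state=seed, covariance_type="full"
        ).fit(logv)
        bics[k] = float(gm.bic(logv))
    kbest = min(bics, key=bics.get)
    gm = GaussianMixture(
        n_components=kbest, n_init=5, random_state=seed, covariance_type="full"
    ).fit(logv)
    order = np.argsort(gm.means_.ravel())
    return KsPeakModel(
        weights=gm.weights_[order],
        log_means=gm.means_.ravel()[order],
        log_sds=np.sqrt(gm.covariances_.ravel()[order]),
        n_components=kbest,
        bic=bics,
    )


# ----------------------------------------------------------------------
# collinear gene-tree monophyly test


@dataclass
class WGDTreeTestResult:
    species_pair: tuple[str, str]
    n_trees_evaluated: int
    n_supporting_independent: int
    n_skipped: int

    @property
    def fraction(self) -> float:
        if self.n_trees_evaluated == 0:
            return float("nan")
        return self.n_supporting_independent / self.n_trees_evaluated


def _default_species_of(label: str) -> str:
    return label.split("|", 1)[0]


def _splits(tree: dendropy.Tree) -> list[frozenset]:
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 0 < len(below) < len(leaves):
            out.append(below)
    return out


def collinear_tree_wgd_test(
    gene_trees: Sequence[str],
    species_pair: tuple[str, str],
    seed: int = 0,
    species_of: Callable[[str], str] = _default_species_of,
) -> WGDTreeTestResult:
    """Per collinear gene tree, root on a random copy of one species
    (alternating which species roots, seeded) and test whether the other
    species' retained copies form a monophyletic clade — evidence that the
    duplications post-date the split (independent WGDs).

    Monophyly under rooting at leaf r holds iff some split of the unrooted
    tree isolates exactly the other species' copies on the side away from r.
    Trees lacking a rootable copy or with fewer than two copies of the
    non-rooting species are skipped and tallied.
    """
    p, q = species_pair
    rng = np.random.default_rng(seed)
    n_eval = n_support = n_skip = 0
    for t_idx, nwk in enumerate(gene_trees):
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        rooter, other = (p, q) if t_idx % 2 == 0 else (q, p)
        root_copies = [l for l in leaves if species_of(l) == rooter]
        other_copies = frozenset(l for l in leaves if species_of(l) == other)
        if not root_copies or len(other_copies) < 2:
            n_skip += 1
            continue
        r = root_copies[int(rng.integers(len(root_copies)))]
        mono = False
        for side in _splits(tree):
            inside = side if r not in side else frozenset(leaves) - side
            if inside == other_copies:
                mono = True
                break
        n_eval += 1
        n_support += int(mono)
    return WGDTreeTestResult(
        species_pair=(p, q),
        n_trees_evaluated=n_eval,
        n_supporting_independent=n_support,
        n_skipped=n_skip,
    )
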