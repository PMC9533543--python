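"""Block chaining, collinearity matrix, clustering and syntenic depth."""

import itertools

import numpy as np
import pandas as pd
import pytest

from karyoevo.genome import apply_polyploidy, simulate_ancestor
from karyoevo.scenarios import all_blocks, moderate_dataset, tables_from
from karyoevo.synteny import (
    CollinearityMatrix,
    GeneOrderTable,
    build_collinearity_matrix,
    cluster_chromosomes,
    collinearity_ratio,
    detect_blocks,
    syntenic_depth,
    z_normalize,
)


def _table(species, chrom_families):
    rows = []
    for chrom, fams in chrom_families.items():
        for i, f in enumerate(fams):
            rows.append((chrom, i, f"{species}.{chrom}.{i}", f, "+"))
    return GeneOrderTable(species, pd.DataFrame(rows, columns=GeneOrderTable.COLUMNS))


# ----------------------------------------------------------------------
# chaining


class TestDetectBlocks:
    def test_identity(self):
        fams = [f"f{i}" for i in range(10)]
        a = _table("A", {"c1": fams})
        b = _table("B", {"c1": fams})
        blocks = detect_blocks(a, b, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 10
        assert blocks[0].orientation == 1

    def test_reversal(self):
        fams = [f"f{i}" for i in range(10)]
        a = _table("A", {"c1": fams})
        b = _table("B", {"c1": fams[::-1]})
        blocks = detect_blocks(a, b, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == -1

    def test_two_shuffled_runs(self):
        a = _table("A", {"c1": [f"f{i}" for i in range(20)]})
        b = _table(
            "B",
            {"c1": [f"f{i}" for i in range(5)] + [f"g{i}" for i in range(5)]
            + [f"f{i}" for i in range(10, 15)]},
        )
        blocks = detect_blocks(a, b, min_anchors=5, max_gap=4)
        spans = sorted(blk.span_a() for blk in blocks)
        assert len(blocks) == 2
        assert spans == [(0, 4), (10, 14)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            _table("A", {})

    def test_each_block_passes_validator(self, moderate_run):
        _, _, blocks = moderate_run
        for blk in blocks[::7]:
            blk.validate(min_anchors=5, max_gap=25)


def _exhaustive_best_chain(anchors, max_gap):
    """Brute-force optimum over all monotone gap-bounded chains (both
    orientations); exponential, for <= 20-gene inputs only."""
    best = 0

    def extend(chain, remaining, orient):
        nonlocal best
        best = max(best, len(chain))
        for idx, (a, b) in enumerate(remaining):
            if chain:
                pa, pb = chain[-1]
                if not (pa < a <= pa + max_gap + 1):
                    continue
                if orient > 0 and not (pb < b <= pb + max_gap + 1):
                    continue
                if orient < 0 and not (pb > b >= pb - max_gap - 1):
                    continue
            extend(chain + [(a, b)], remaining[idx + 1 :], orient)

    srt = sorted(anchors)
    for orient in (+1, -1):
        extend([], srt, orient)
    return best


@pytest.mark.parametrize("seed", range(6))
def test_chaining_matches_exhaustive_oracle(seed):
    """On tiny genomes the first extracted chain attains the enumeration
    optimum."""
    rng = np.random.default_rng(seed)
    n = 14
    fams = [f"f{i}" for i in range(n)]
    perm = rng.permutation(n)
    a = _table("A", {"c1": fams})
    b = _table("B", {"c1": [fams[i] for i in perm]})
    max_gap = 3
    blocks = detect_blocks(a, b, min_anchors=1, max_gap=max_gap)
    anchors = [(i, int(np.flatnonzero(perm == i)[0])) for i in range(n)]
    oracle = _exhaustive_best_chain(anchors, max_gap)
    assert max(blk.n_anchors for blk in blocks) == oracle


# ----------------------------------------------------------------------
# ratios and Z-transformation


class TestCollinearityRatio:
    @pytest.mark.parametrize(
        "cn,ni,nj,expected", [(100, 100, 100, 1.0), (0, 50, 70, 0.0), (50, 80, 120, 0.5)]
    )
    def test_values(self, cn, ni, nj, expected):
        assert collinearity_ratio(cn, ni, nj) == pytest.approx(expected)

    def test_cn_exceeding_min_rejected(self):
        with pytest.raises(ValueError):
            collinearity_ratio(60, 50, 100)

    def test_matrix_symmetry(self, moderate_run):
        _, tables, blocks = moderate_run
        m = build_collinearity_matrix(tables, blocks)
        assert np.allclose(m.x.to_numpy(), m.x.to_numpy().T)
        assert (m.x.to_numpy() >= 0).all() and (m.x.to_numpy() <= 1).all()


class TestZNormalize:
    def test_three_point_row(self):
        x = pd.DataFrame(
            [[0.0, 0.2, 0.4, 0.6], [0.2, 0.0, 0.3, 0.5], [0.4, 0.3, 0.0, 0.1], [0.6, 0.5, 0.1, 0.0]],
            index=list("abcd"), columns=list("abcd"),
        )
        m = CollinearityMatrix(x=x, cn=x * 0, n=pd.Series(1, index=list("abcd")))
        z = z_normalize(m).zx
        assert np.allclose(z.loc["a", ["b", "c", "d"]], [-1.0, 0.0, 1.0])

    def test_constant_row_errors(self):
        x = pd.DataFrame(
            [[0, 0.5, 0.5], [0.5, 0, 0.2], [0.5, 0.2, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        m = CollinearityMatrix(x=x, cn=x * 0, n=pd.Series(1, index=list("abc")))
        with pytest.raises(ValueError, match="'a'"):
            z_normalize(m)

    def test_rows_standardised(self, moderate_run):
        _, tables, blocks = moderate_run
        z = z_normalize(build_collinearity_matrix(tables, blocks)).zx.to_numpy()
        for i in range(len(z)):
            row = np.delete(z[i], i)
            assert abs(row.mean()) < 1e-10
            assert abs(row.std(ddof=1) - 1) < 1e-10


# ----------------------------------------------------------------------
# clustering


class TestClustering:
    def test_wgd_copies_share_cluster(self):
        anc = simulate_ancestor(4, 60)
        dup, _ = apply_polyploidy(anc, 2, 1.0, seed=0)
        t = GeneOrderTable.from_genome(dup)
        blocks = detect_blocks(t, t)
        m = build_collinearity_matrix([t], blocks)
        res = cluster_chromosomes(m, k=4)
        labels = res.labels
        for c in range(1, 5):
            assert labels[f"ancestor:chr{c}.0"] == labels[f"ancestor:chr{c}.1"]

    def test_moderate_scenario_recovers_seven(self, moderate_run):
        ds, tables, blocks = moderate_run
        m = build_collinearity_matrix(tables, blocks)
        res = cluster_chromosomes(m, k="auto")
        assert res.k == 7

    def test_recovery_over_seeds(self):
        """Silhouette-selected k equals the true ancestral count in >= 9/10
        seeded moderate scenarios."""
        hits = 0
        for seed in range(2, 12):
            ds = moderate_dataset(seed=seed)
            tables = tables_from(ds)
            blocks = all_blocks(tables)
            m = build_collinearity_matrix(tables, blocks)
            hits += cluster_chromosomes(m, k="auto").k == 7
        assert hits >= 9

    def test_k_exceeding_n_rejected(self):
        x = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        m = CollinearityMatrix(x=x, cn=x * 0, n=pd.Series(1, index=list("abc")))
        with pytest.raises(ValueError):
            cluster_chromosomes(m, k=5)


# ----------------------------------------------------------------------
# syntenic depth


class TestSyntenicDepth:
    def test_identity_one_to_one(self):
        anc = simulate_ancestor(3, 100)
        t = GeneOrderTable.from_genome(anc)
        other = GeneOrderTable("other", t.df)
        blocks = detect_blocks(t, other)
        assert syntenic_depth(blocks, t, other) == (1, 1)

    def test_wgd_two_to_one(self):
        anc = simulate_ancestor(7, 100)
        dup, _ = apply_polyploidy(anc, 2, 1.0, seed=0)
        dup = dup.copy("dup")
        ta = GeneOrderTable.from_genome(dup)
        tb = GeneOrderTable.from_genome(anc)
        blocks = detect_blocks(ta, tb)
        assert syntenic_depth(blocks, ta, tb) == (2, 1)

    def test_wgd_with_loss_still_modal_two(self):
        anc = simulate_ancestor(7, 200)
        dup, _ = apply_polyploidy(anc, 2, 0.7, seed=3)
        dup = dup.copy("dup")
        ta = GeneOrderTable.from_genome(dup)
        tb = GeneOrderTable.from_genome(anc)
        blocks = detect_blocks(ta, tb)
        assert syntenic_depth(blocks, ta, tb) == (2, 1)

    def test_no_blocks_rejected(self):
        anc = simulate_ancestor(1, 10)
        t = GeneOrderTable.from_genome(anc)
        with pytest.raises(ValueError):
            syntenic_depth([], t, t)
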