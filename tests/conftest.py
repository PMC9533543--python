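import pytest

from karyoevo.genome import simulate_ancestor
from karyoevo.aek import AEKChromosome
from karyoevo.scenarios import all_blocks, moderate_dataset, tables_from


@pytest.fixture(scope="session")
def small_ancestor():
    """7 x 80-gene ancestor used across fusion and projection tests."""
    return simulate_ancestor(7, 80)


@pytest.fixture(scope="session")
def true_aeks(small_ancestor):
    """The ancestor itself expressed as ancestral chromosomes (ground truth)."""
    return [
        AEKChromosome(aek_id=c + 1, families=[g.family_id for g in chrom.genes])
        for c, chrom in enumerate(small_ancestor.chromosomes)
    ]


@pytest.fixture(scope="session")
def true_aek_lengths(true_aeks):
    return {a.aek_id: len(a) for a in true_aeks}


@pytest.fixture(scope="session")
def moderate_run():
    """One moderate six-genome dataset with its tables and all blocks."""
    ds = moderate_dataset(seed=1)
    tables = tables_from(ds)
    blocks = all_blocks(tables)
    return ds, tables, blocks
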