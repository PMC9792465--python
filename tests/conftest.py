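import numpy as np
import pytest

import ohnofate as of


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded cohort shared by read-only tests: 2 chromosome pairs,
    4 cell types x 50 cells, with every fate represented."""
    cfg = of.SimConfig(
        n_chrom_pairs=2,
        genes_per_chrom=40,
        n_cell_types=4,
        cells_per_type=50,
        seed=42,
    )
    genome = of.simulate_genomes(cfg)
    matrix, truth = of.simulate_counts(cfg, genome.true_pairs)
    of.normalize_counts(matrix)
    return cfg, genome, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
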