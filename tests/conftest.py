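import numpy as np
import pytest

from conect.pipeline import run_classification
from conect.simulate import (
    generate_genome_and_genes,
    paperlike_fixture,
    simulate_probe_panel,
)
from conect.tiling import tiling_pipeline

SEED = 17


@pytest.fixture(scope="session")
def fixture17():
    """Noise-free planted fixture: 5 features x 7 categories + background."""
    return paperlike_fixture(seed=SEED, n_background=60)


@pytest.fixture(scope="session")
def classified17(fixture17):
    return run_classification(fixture17.genome, fixture17.genes, fixture17.fragments)


@pytest.fixture(scope="session")
def noisy_fixture():
    """Same plant, 1% substitution errors, three supporting fragments each."""
    return paperlike_fixture(seed=SEED, n_background=40, coverage=3, error_rate=0.01)


@pytest.fixture(scope="session")
def noisy_classified(noisy_fixture):
    return run_classification(noisy_fixture.genome, noisy_fixture.genes, noisy_fixture.fragments)


@pytest.fixture(scope="session")
def tiling_sim():
    """Probe panel over 50 expressed / 50 silent genes (GC bias on) + caller result."""
    genome, genes = generate_genome_and_genes(n_chrom=2, chrom_len=350_000, n_genes=100, seed=SEED)
    labels = {g.gene_id: (i % 2 == 0) for i, g in enumerate(genes)}
    panel = simulate_probe_panel(genome, genes, labels, gc_bias=0.1, seed=SEED)
    result = tiling_pipeline(panel, genes)
    return genes, labels, panel, result


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
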