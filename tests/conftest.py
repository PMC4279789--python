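import numpy as np
import pytest

from locusboost.simulate import SimulationConfig, make_genome, make_trait


SMALL = SimulationConfig(
    n_genes=400,
    n_loci=8,
    genes_per_locus=(4, 10),
    n_features=60,
    n_planted=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_trait():
    """A small synthetic trait bundle shared across fast tests."""
    rng = np.random.default_rng(SMALL.seed)
    genome = make_genome(SMALL, rng)
    return make_trait(genome, SMALL, rng)


@pytest.fixture(scope="session")
def small_loci(small_trait):
    return small_trait.build_loci()
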