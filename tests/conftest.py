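import numpy as np
import pytest

from barfit import SampleMeta, make_genome, make_library


@pytest.fixture(scope="session")
def small_genome():
    """100-gene genome on 3 replicons, ~100 kb total."""
    return make_genome(n_genes=100, mean_gene_len=900, intergenic_len=100, seed=11)


@pytest.fixture(scope="session")
def small_library(small_genome):
    """500 uniformly placed neutral mutants on the small genome."""
    return make_library(small_genome, n_mutants=500, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_point_samples(condition="fructose", regime="continuous", generations=(0.0, 8.0), replicates=(1, 2)):
    return [
        SampleMeta(f"{condition}_g{g:g}_r{r}", condition, regime, g, r)
        for r in replicates
        for g in generations
    ]
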