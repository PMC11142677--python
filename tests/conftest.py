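import numpy as np
import pytest

from redqueen.genome_model import AffinityDistribution, Population, create_allele


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pop(rng):
    """N=6 population, two segregating alleles with modest target sets."""
    pop = Population.founder(6, 25, AffinityDistribution(0.5), rng, L=20_000)
    b = create_allele(pop, pop.affinity_dist, rng)
    pop.hap_allele[:4] = b.row
    pop.gc(force=True)
    return pop


def constant_affinity_population(N, h, y, rng, n_alleles=1, L=None):
    """Population whose alleles all have identical site affinities y."""
    pop = Population.founder(N, h, AffinityDistribution(y), rng, L=L)
    for a in pop.registry.values():
        a.affinities[:] = y
    for _ in range(n_alleles - 1):
        a = create_allele(pop, pop.affinity_dist, rng)
        a.affinities[:] = y
    # rebuild column affinities after the in-place edit
    for a in pop.registry.values():
        pop.col_aff[pop.allele_cols[a.row]] = a.affinities
    pop.version += 1
    return pop
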