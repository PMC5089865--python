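import numpy as np
import pytest

from esrsim import HaplotypeProportions, PhenotypeFitness, baseline


@pytest.fixture
def baseline_scenario():
    return baseline()


@pytest.fixture
def baseline_fitness():
    return PhenotypeFitness(F_S=0.20, F_R=0.60, F_D=0.45, F_RD=0.45)


@pytest.fixture
def baseline_pool():
    """Linkage-equilibrium haplotype pool at the reference allele prevalences."""
    return HaplotypeProportions.from_allele_freqs(0.005, 0.25)


def random_pool(rng: np.random.Generator) -> HaplotypeProportions:
    return HaplotypeProportions.from_array(rng.dirichlet(np.ones(4)))


def random_fitness(rng: np.random.Generator) -> PhenotypeFitness:
    return PhenotypeFitness(*rng.uniform(0.0, 1.0, size=4))
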