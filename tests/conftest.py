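import numpy as np
import pytest

from asvgrm import GenotypeMatrix, PhenotypeVector, grm_asv, simulate_genotypes, simulate_trait


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_g():
    """Single-marker genotype column (0, 1, 2): the smallest polymorphic case."""
    return GenotypeMatrix.from_array([[0], [1], [2]])


@pytest.fixture
def random_g(rng):
    """Moderately sized random dosage matrix (polymorphic w.p. ~1)."""
    return GenotypeMatrix.from_array(rng.integers(0, 3, size=(25, 60)).astype(float))


@pytest.fixture
def fitted_dataset():
    """Simulated population + trait + ASV kernel for REML-level tests."""
    G = simulate_genotypes(120, 300, H=0.5, seed=7)
    trait = simulate_trait(G, h2=0.5, seed=8)
    y = PhenotypeVector(trait.y, G.entry_ids)
    return G, y, grm_asv(G)
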