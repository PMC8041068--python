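import numpy as np
import pytest

from fastrr import GenotypeMatrix, SimConfig, generate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Desk-scale scenario: one QTN on a 300 x 800 panel."""
    return SimConfig(
        n_individuals=300,
        n_markers=800,
        qtn_positions=(98,),
        qtn_effects=(0.7398,),
        polygenic_multiplier=2.0,
    )


@pytest.fixture
def small_geno(small_config):
    return generate_genotypes(small_config, seed=11)


@pytest.fixture
def toy_geno(rng):
    """Tiny dense matrix for explicit-loop oracles."""
    mat = rng.choice([-1.0, 1.0], size=(8, 5))
    return GenotypeMatrix(matrix=mat)
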