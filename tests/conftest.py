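import numpy as np
import pytest

from mito_sre import mapping, simulate


@pytest.fixture(scope="session")
def small_genome():
    """A 12 kb genome with 4 protein-coding genes on both strands."""
    seq, models = simulate.generate_genome(
        12000, 4, both_strands=True, seed=7, read_length=100
    )
    return seq, models


@pytest.fixture(scope="session")
def genome_obj(small_genome):
    seq, _ = small_genome
    return mapping.Genome("mito", seq)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
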