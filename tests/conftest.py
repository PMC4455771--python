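import numpy as np
import pytest

from pbrhet.codon_alignment import CodonAlignment, PbrMask
from pbrhet.synthetic_data import SynthConfig, evolve_alignment, generate_genealogy


@pytest.fixture(scope="session")
def small_synth():
    """A 12-allele synthetic dataset at the default study-like conditions."""
    cfg = SynthConfig(n_alleles=12, seed=3)
    tree = generate_genealogy(cfg)
    alignment, truth = evolve_alignment(tree, cfg)
    return cfg, tree, alignment, truth


@pytest.fixture
def tiny_alignment():
    records = {
        "A": "ATGGGTTTT",
        "B": "ATGGTTTTT",
        "C": "ATGGGTTTC",
        "D": "ATGGTTTTC",
    }
    return CodonAlignment(records, PbrMask((2,), "test"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
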