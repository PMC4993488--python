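import numpy as np
import pytest

from metacomp import simulate
from metacomp.records import SequenceRecord

MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def substitute(seq: str, positions) -> str:
    """Deterministically substitute the given 0-based positions."""
    chars = list(seq)
    for p in positions:
        chars[p] = MUT[chars[p]]
    return "".join(chars)


@pytest.fixture(scope="session")
def genome_20kb() -> SequenceRecord:
    return simulate.simulate_genome(20000, 0.55, seed=11, genome_id="g20")


@pytest.fixture(scope="session")
def planted_genome():
    """A 60 kb genome with 50 planted genes and its catalog."""
    g = simulate.simulate_genome(60000, 0.61, seed=21, genome_id="pg")
    return simulate.plant_genes(g, 50, length_mean=900, length_sd=100, seed=21)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
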