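import numpy as np
import pytest

from tfdna import (
    CS_CONSENSUS,
    DuplexSpec,
    ToyComplexSpec,
    TitrationProtocol,
    build_ideal_bdna,
    make_toy_complex,
    pair_duplex,
)


@pytest.fixture(scope="session")
def cs_duplex():
    """Ideal B-form duplex of the 22-mer consensus operator."""
    return build_ideal_bdna(DuplexSpec(sequence=CS_CONSENSUS))


@pytest.fixture(scope="session")
def cs_pairs(cs_duplex):
    return pair_duplex(cs_duplex, "A", "B")


@pytest.fixture(scope="session")
def toy_pair():
    """Apo/bound toy complex with the ledger (retained 5, disrupted 10, formed 9)."""
    return make_toy_complex(ToyComplexSpec(5, 10, 9, seed=11))


@pytest.fixture(scope="session")
def protocol():
    """Default titration: 25 x 1.5 ul of 120 uM duplex into 10 uM dimer, 200 ul."""
    return TitrationProtocol()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
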