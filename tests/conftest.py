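import numpy as np
import pytest

from plmvep.backend import ALPHABET, ProteinSequence, make_synthetic_backend
from plmvep.fixtures import FixtureSpec, generate_fixtures


def random_protein(rng, length, seq_id="prot"):
    return ProteinSequence(
        id=seq_id, residues="".join(rng.choice(list(ALPHABET), size=length))
    )


@pytest.fixture
def backend7():
    return make_synthetic_backend(7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def bundle1():
    """Default-scale fixture bundle, shared across tests (read-only)."""
    return generate_fixtures(FixtureSpec(seed=1))
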