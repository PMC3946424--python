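import numpy as np
import pytest

from palinclip.hairpinsim import generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """2 kb balanced-composition genome shared across tests."""
    return generate_genome(2000, 0.5, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
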