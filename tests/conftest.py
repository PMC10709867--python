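import numpy as np
import pytest

from dualcut import ScoringScheme, random_junction_reference

BASES = "ACGT"


@pytest.fixture(scope="session")
def ref0():
    """A reproducible PAM-out deletion junction (both flanks carry -4/-5/-6)."""
    ref, _, _ = random_junction_reference(seed=0)
    return ref


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(13)


def random_dna(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))
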