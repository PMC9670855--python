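import numpy as np
import pytest

from dropscape import ProteinSequence, SyntheticSpec, generate_sequence, profile_sequence
from dropscape.seq_io import CANONICAL_AA

AA = list(CANONICAL_AA)


def random_sequence(rng, length, offset=1, ident="rand"):
    return ProteinSequence(
        id=ident, residues="".join(rng.choice(AA, size=length)), numbering_offset=offset
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lc_sequence():
    """Synthetic low-complexity domain in the 262-414 numbering frame."""
    return generate_sequence(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def lc_profile(lc_sequence):
    return profile_sequence(lc_sequence)
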