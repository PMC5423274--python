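import numpy as np
import pytest

from gbskit.enzymes import RestrictionEnzyme


@pytest.fixture(scope="session")
def toy_enzyme():
    """EcoRI-like toy enzyme: GAATTC, cut after the first base (G^AATTC)."""
    return RestrictionEnzyme("toyE", "GAATTC", 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170509)


def random_sequence(rng, length, gc=0.4):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
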