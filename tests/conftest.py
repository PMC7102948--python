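import numpy as np
import pytest

from mirsig.signature import default_signature_model


@pytest.fixture
def model():
    return default_signature_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_21mer(gc_positions, gc_base="G", au_base="A"):
    """A 21-mer with G/C at the given 1-based positions, A/U elsewhere."""
    return "".join(gc_base if i in gc_positions else au_base
                   for i in range(1, 22))
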