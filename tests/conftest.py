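import pytest

from moclosim.digestion import BUILTIN_TYPE_IIS
from moclosim.fixtures import make_kit
from moclosim.sequence_io import DnaMolecule

#: worked example: BsaI sites facing inward around an AATG/CCC/GCTT part
WORKED_CIRCLE_SEQ = "GGTCTCAAATGCCCGCTTTGAGACCTTTT"


@pytest.fixture(scope="session")
def bsai():
    return BUILTIN_TYPE_IIS["BsaI"]


@pytest.fixture
def worked_circle():
    return DnaMolecule("circ29", WORKED_CIRCLE_SEQ, topology="circular")


@pytest.fixture(scope="session")
def kit32(bsai):
    """3 positions x 2 parts, BsaI, seed 1 — the standard small kit."""
    return make_kit(3, 2, bsai, seed=1)
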