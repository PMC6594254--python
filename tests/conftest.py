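import numpy as np
import pytest

from seqvis3d import Sequence, normalize_sequence, spiral_embed
from seqvis3d.synthetic import random_sequence


@pytest.fixture
def flat_lattice_5():
    """Full 5x5 lattice with constant elevation (poly-A sequence)."""
    return spiral_embed(normalize_sequence("A" * 25, id="flat"))


@pytest.fixture
def mir146a_like() -> Sequence:
    """Synthetic stand-in for a 99-nt precursor with an A at position 50.

    This is a random sequence, not any real miRNA: only its length and the
    reference base at the polymorphic position mimic the real fixture.
    """
    seq = random_sequence(99, seed=146, id="mir146a-like-synthetic")
    residues = seq.residues[:49] + "A" + seq.residues[50:]
    return Sequence(id=seq.id, residues=residues)


def pytest_configure(config):
    np.seterr(all="raise", under="ignore")
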