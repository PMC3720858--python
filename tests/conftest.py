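import numpy as np
import pytest

from confplan import make_hinge_toy
from confplan.backbone import build_backbone


@pytest.fixture(scope="session")
def hinge():
    """Small helix-loop-helix transition problem (21 residues, loop 9-13)."""
    return make_hinge_toy(seed=1)


@pytest.fixture(scope="session")
def helical_chain():
    """20-residue near-helical chain with a distinctive central loop."""
    dih = np.tile((-57.0, -47.0), (20, 1))
    dih[8:13] = (-120.0, 120.0)
    return build_backbone("A" * 20, dih)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
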