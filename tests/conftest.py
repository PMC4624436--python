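import numpy as np
import pytest

from altconf.benchmark import build_backbone_chain
from altconf.flips import load_flip_centroids
from altconf.model import load_rotamer_library

LOOP_PHIPSI = (-80.0, 130.0)


@pytest.fixture(scope="session")
def library():
    return load_rotamer_library()


@pytest.fixture(scope="session")
def centroids():
    return load_flip_centroids()


@pytest.fixture()
def loop_chain():
    """7-residue ideal poly-Ala loop (flip-eligible everywhere)."""
    return build_backbone_chain(["ALA"] * 7, [LOOP_PHIPSI] * 7)


@pytest.fixture()
def helix_chain():
    """9-residue ideal alpha helix (flip sampling suppressed)."""
    return build_backbone_chain(["ALA"] * 9, [(-57.0, -47.0)] * 9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
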