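import numpy as np
import pytest

import brainclock as bc


@pytest.fixture(scope="session")
def connectome16():
    """Small hub-structured connectome for fast model-based tests."""
    return bc.generate_structural_connectome(16, 0.25, 0.4, seed=2)


@pytest.fixture(scope="session")
def connectome78():
    """Study-scale connectome (78 cortical regions)."""
    return bc.generate_structural_connectome(78, 0.2, 0.3, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def two_node_connectome(weight=1.0):
    w = np.array([[0.0, weight], [weight, 0.0]])
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    return bc.StructuralConnectome(w, coords, np.array([True, False]))
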