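import numpy as np
import pytest

from ecsrd.grid import build_grid
from ecsrd.kinetics import Reaction, Species

#: the sigmoidal astrocyte-uptake forward rate with its published constants
KF_EXPR = "0.0008/(1.0 + exp(-(k - 15.0)/1.15))"
KB = 0.0008


@pytest.fixture
def tiny_grid():
    """Single-digit voxel grid with the standard tissue parameters."""
    return build_grid(0, 0, 0, 30, 30, 30, 10, 0.2, 1.6)


@pytest.fixture
def hetero_grid():
    """Small grid with smoothly varying alpha and tortuosity."""
    return build_grid(
        0, 0, 0, 210, 210, 210, 10,
        lambda x, y, z: 0.08 + 0.12 * x / 210.0,
        lambda x, y, z: 1.4 + 0.4 * y / 210.0,
    )


@pytest.fixture
def buffer_reaction():
    return Reaction("k + A", "AK", KF_EXPR, KB)


@pytest.fixture
def buffer_species():
    return [
        Species("k", d=2.62, charge=1,
                initial=lambda x, y, z: np.where(x < 70, 30.0, 3.5)),
        Species("A", d=0.0, initial=10.0),
        Species("AK", d=0.0, initial=0.0),
    ]
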