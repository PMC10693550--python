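import numpy as np
import pytest

from ccphase.constructs import parse_construct
from ccphase.engine import Configuration
from ccphase.forcefield import ForceFieldParams, InteractionMatrix
from ccphase.topology import build_system_topology


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def matrix(ff):
    return InteractionMatrix.default(ff)


def straight_chain_config(constructs, box, seed=0, spacing=0.38, separation=0.7, jitter=0.01):
    """Chains as parallel straight rods with small jitter, offset laterally."""
    top = build_system_topology([(parse_construct(c), 1) for c in constructs])
    rng = np.random.default_rng(seed)
    pos = np.zeros((top.n_beads, 3))
    for c in range(top.n_chains):
        sl = top.chain_slice(c)
        n = sl.stop - sl.start
        pos[sl, 0] = spacing * np.arange(n) + 1.0
        pos[sl, 1] = 1.0 + separation * c
        pos[sl, 2] = 1.0
    if jitter:
        pos += rng.normal(0.0, jitter, pos.shape)
    box = np.asarray(box, float)
    return Configuration(pos, np.zeros_like(pos), box, top)


@pytest.fixture
def two_coil_config():
    """One S1h and one S2h single-coil chain, side by side in register."""

    def make(separation=0.7, box=(12.0, 12.0, 12.0), seed=0):
        return straight_chain_config(["(S1h)1", "(S2h)1"], box, seed=seed,
                                     separation=separation)

    return make
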