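import numpy as np
import pytest

import benthox as bx

#: fast solve settings shared by tests that only need a qualitatively
#: converged field (coarse sediment grid, short spin-up)
FAST = dict(n_cycles=1, spinup_cycles=3, dt=0.005, points_per_cycle=100)


@pytest.fixture(scope="session")
def cold_field():
    return bx.simulate_diel(bx.make_scenario("cold"), n_cycles=2, spinup_cycles=5)


@pytest.fixture(scope="session")
def warm_field():
    return bx.simulate_diel(bx.make_scenario("warm"), n_cycles=2, spinup_cycles=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
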