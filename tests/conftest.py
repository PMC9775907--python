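import numpy as np
import pytest

import motifres as mr


@pytest.fixture(scope="session")
def ts_small():
    """A small isolated toggle-switch ensemble shared across tests."""
    return mr.simulate_ensemble(mr.motif_topology("TS"), 400, 25, seed=11)


@pytest.fixture(scope="session")
def tt_small():
    """A small isolated toggle-triad ensemble shared across tests."""
    return mr.simulate_ensemble(mr.motif_topology("TT"), 400, 25, seed=12)


@pytest.fixture(scope="session")
def embedded_ts():
    """One embedded toggle-switch network and its ensemble."""
    topo = mr.generate_embedded_network("TS", 5, 2, seed=21)
    table = mr.simulate_ensemble(topo, 150, 10, seed=22, t_max=300)
    return topo, table


@pytest.fixture(scope="session")
def embedded_tt():
    """One embedded toggle-triad network and its ensemble."""
    topo = mr.generate_embedded_network("TT", 5, 2, seed=31)
    table = mr.simulate_ensemble(topo, 150, 10, seed=32, t_max=300)
    return topo, table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
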