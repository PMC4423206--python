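import numpy as np
import pytest

from ecorange.simulator import SimConfig, run_simulation


@pytest.fixture(scope="session")
def reference_runs():
    """20 replicate range expansions at the reference parameter set
    (a_max=0.03, e=700, invb_max=0.02, lambda0=4, K=50, mu=0, d_max=3).

    Session-scoped: these runs back all directional checks on the spatial
    profiles (density, dispersal and foraging-efficiency gradients).
    """
    seeds = np.random.SeedSequence(1234).generate_state(20) & 0x7FFFFFFF
    return [run_simulation(SimConfig(seed=int(s)), record_every=5) for s in seeds]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
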