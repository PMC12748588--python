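import numpy as np
import pytest

from coevodock import benchmark


@pytest.fixture(scope="session")
def docking_runs():
    """Restrained and control docking trajectories shared across tests.

    Five seeded restrained runs and three no-restraint controls under the
    benchmark conditions; expensive, so computed once per session.
    """
    restrained = [benchmark.run_docking_benchmark(seed, restrained=True) for seed in range(1, 6)]
    control = [benchmark.run_docking_benchmark(seed, restrained=False) for seed in range(1, 4)]
    return {"restrained": restrained, "control": control}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
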