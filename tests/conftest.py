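import numpy as np
import pytest

from plastome.simulate import SimulationConfig, simulate_plastome_set

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic study set shared across tests."""
    return simulate_plastome_set(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def reference(sim_default):
    return sim_default.plastomes[0]
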