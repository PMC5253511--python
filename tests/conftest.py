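import numpy as np
import pytest

from chemotax import SimulationConfig, generate
from chemotax.chem_fingerprints import Fingerprint


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def synthetic():
    """Default study conditions: 5 taxa x 6 plants, 20% missingness."""
    return generate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_clean():
    """Noise-free dataset: every plant's relations are its full taxon profile."""
    return generate(SimulationConfig(missingness=0.0, seed=7))


def random_fingerprints(rng, n, length=166, p_on=0.25):
    """Random binary fingerprints; at least one bit set per vector."""
    fps = []
    for i in range(n):
        bits = (rng.random(length) < p_on).astype(np.uint8)
        if bits.sum() == 0:
            bits[int(rng.integers(length))] = 1
        fps.append(Fingerprint(f"m{i:04d}", bits))
    return fps
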