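import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noodiag import SpinOccupancySet

settings.register_profile(
    "noodiag",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("noodiag")

GLOBAL_SEED = 20240917


@pytest.fixture
def rng():
    return np.random.default_rng(GLOBAL_SEED)


def random_occupancy_set(rng, max_orbitals=12, n_mixes=8, label=""):
    """Random physical occupancy set: trace equals the electron count exactly.

    Starts from an idempotent aufbau filling and applies pairwise
    occupation transfers (what off-diagonal 1-RDM rotations do to the
    diagonal), which keeps every entry in [0, 1] and conserves each
    channel's electron count.
    """
    channels = []
    counts = []
    for _ in range(2):
        m = int(rng.integers(2, max_orbitals + 1))
        n = int(rng.integers(1, m))
        occ = np.zeros(m)
        occ[:n] = 1.0
        for _ in range(n_mixes):
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            delta = rng.uniform(0, 1) * min(occ[i], 1.0 - occ[j])
            occ[i] -= delta
            occ[j] += delta
        channels.append(occ)
        counts.append(n)
    return SpinOccupancySet(
        occ_alpha=channels[0],
        occ_beta=channels[1],
        n_alpha=counts[0],
        n_beta=counts[1],
        label=label,
    )


@pytest.fixture
def occupancy_factory():
    return random_occupancy_set
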