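import numpy as np
import pytest

from uninet.core import Network, Partition, correlation_network, validate_network
from uninet.synth import SynthSpec, synth_structural, synth_timeseries


@pytest.fixture(scope="session")
def modular_data():
    """Planted 4-module correlation data (n=60, p=1000, defaults)."""
    X, truth = synth_timeseries(SynthSpec(seed=1))
    return X, truth


@pytest.fixture(scope="session")
def modular_network(modular_data) -> Network:
    return correlation_network(modular_data[0])


@pytest.fixture(scope="session")
def structural_network() -> Network:
    return synth_structural(n=100, seed=1)


@pytest.fixture()
def two_cliques() -> Network:
    """Two disconnected 2-cliques (binary, zero diagonal)."""
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 1.0
    W[2, 3] = W[3, 2] = 1.0
    return validate_network(W, flavor="structural")


def random_partitions(n: int, k: int, count: int, seed: int = 0):
    """Seeded random k-partitions with every module non-empty."""
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(count):
        labels = rng.integers(0, k, size=n)
        for h in range(k):
            if not np.any(labels == h):
                big = np.flatnonzero(np.bincount(labels, minlength=k)[labels] > 1)
                labels[rng.choice(big)] = h
        parts.append(Partition(labels, k))
    return parts
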