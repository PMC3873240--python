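import numpy as np
import pytest

from admixdemo.containers import GenomeMap, MigrationHistory


@pytest.fixture(scope="session")
def genome():
    return GenomeMap.default_autosomes()


@pytest.fixture(scope="session")
def small_genome():
    """A 6-Morgan toy genome for fast painting tests."""
    return GenomeMap(names=("chrA", "chrB", "chrC"),
                     lengths_cm=(250.0, 200.0, 150.0))


@pytest.fixture(scope="session")
def two_way_pulse():
    """Single 50/50 NAT-EUR founding pulse 10 generations ago."""
    m = np.zeros((11, 3))
    m[10] = [0.5, 0.5, 0.0]
    return MigrationHistory(m)


@pytest.fixture(scope="session")
def three_way_history():
    """Founding pulse plus continuing EUR inflow (three ancestries)."""
    m = np.zeros((13, 3))
    m[12] = [0.45, 0.45, 0.10]
    for g in range(2, 12):
        m[g, 1] = 0.01
    return MigrationHistory(m)
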