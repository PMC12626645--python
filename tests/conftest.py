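import numpy as np
import pytest

from netstab.io import CountTable


@pytest.fixture
def small_table() -> CountTable:
    """4 samples x 3 taxa with simple round numbers."""
    counts = np.array(
        [
            [5, 5, 10],
            [2, 2, 4],
            [1, 3, 4],
            [10, 0, 0],
        ]
    )
    return CountTable(counts, ("s1", "s2", "s3", "s4"), ("t1", "t2", "t3"))


@pytest.fixture(scope="session")
def default_synth():
    """One default-configuration synthetic dataset shared across tests."""
    from netstab.synth import SynthConfig, simulate_counts

    cfg = SynthConfig(seed=0)
    table, truth = simulate_counts(cfg)
    return cfg, table, truth
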