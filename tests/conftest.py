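import numpy as np
import pytest

from v2g.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One full simulated dataset at the default study conditions."""
    return simulate_all(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000):
    from v2g.genomic_core import GenomicInterval

    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        end = start + int(rng.integers(1, 500))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, end))
    return out
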