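import numpy as np
import pytest

from damidcall.counting import CountMatrix, GROUP_DAM, GROUP_POI
from damidcall.simulate import (SimulationConfig, simulate_counts,
                                simulate_fragment_map)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 fragments x 4 samples with equal library sizes."""
    counts = np.array([
        [100, 120, 300, 310],
        [50, 55, 48, 52],
        [5, 6, 4, 7],
        [0, 0, 0, 0],
    ])
    return CountMatrix(counts, np.arange(4),
                       ["d1", "d2", "p1", "p2"],
                       [GROUP_DAM, GROUP_DAM, GROUP_POI, GROUP_POI],
                       np.array([1_000_000] * 4))


@pytest.fixture
def small_simulation():
    """2k-fragment simulated dataset with planted binding (seeded)."""
    cfg = SimulationConfig(chromosome_length=520_000, seed=7)
    rng = cfg.rng()
    fmap, truth = simulate_fragment_map(cfg, rng)
    counts = simulate_counts(cfg, fmap, truth, rng)
    return cfg, fmap, truth, counts
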