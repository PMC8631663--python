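import numpy as np
import pytest

import pairseek as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Deterministic 12-sample, 4-taxon table with assorted zeros."""
    counts = np.array(
        [
            [0, 5, 3, 10],
            [2, 0, 7, 1],
            [7, 1, 0, 0],
            [4, 4, 2, 9],
            [0, 0, 5, 3],
            [1, 9, 0, 2],
            [3, 2, 8, 0],
            [6, 0, 1, 4],
            [0, 3, 0, 7],
            [9, 6, 4, 2],
            [2, 7, 6, 0],
            [5, 1, 2, 8],
        ]
    )
    samples = [f"s{i}" for i in range(12)]
    taxa = ["gen_a", "gen_b", "gen_c", "gen_d"]
    return ps.CountTable(samples, taxa, counts)


@pytest.fixture(scope="session")
def sim_table():
    """Mid-sized synthetic cohort reused by slower integration tests."""
    return ps.synthetic_counts(n_samples=120, n_taxa=20, seed=5)
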