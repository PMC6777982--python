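import numpy as np
import pytest

from lagnav.datatypes import CohortConfig
from lagnav.synthetic import gen_connectome, gen_parcellation


@pytest.fixture(scope="session")
def regions6():
    """Small parcellation: 6 homotopic pairs."""
    return gen_parcellation(6, seed=11)


@pytest.fixture(scope="session")
def regions10():
    return gen_parcellation(10, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled cohort for fast end-to-end tests."""
    return CohortConfig(
        n_stroke=8, n_control=6, n_pairs=10, n_timepoints=160, seed=5
    )


@pytest.fixture(scope="session")
def conn10(regions10):
    return gen_connectome(regions10, CohortConfig(n_pairs=10, seed=7))


def random_length_graph(rng, n, p_edge=0.6):
    """Random symmetric length matrix with inf non-edges (test helper)."""
    L = np.full((n, n), np.inf)
    np.fill_diagonal(L, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                L[i, j] = L[j, i] = rng.uniform(0.1, 3.0)
    return L
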