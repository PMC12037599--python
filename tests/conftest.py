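import warnings

import numpy as np
import pytest

from covnet.regions import RegionSet, default_regions
from covnet.simulate import SyntheticSpec, generate_cohort

# small-cohort warnings are expected throughout the toy fixtures
warnings.filterwarnings("ignore", message=".*subjects; correlation estimates.*")


@pytest.fixture(scope="session")
def regions68():
    return default_regions()


@pytest.fixture(scope="session")
def regions6(regions68):
    return RegionSet(regions68.names[:6], regions68.hemispheres[:6])


@pytest.fixture(scope="session")
def regions20(regions68):
    return RegionSet(regions68.names[:20], regions68.hemispheres[:20])


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (null group effect), fixed seed."""
    return generate_cohort(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort(regions6):
    """Tiny 6-region cohort for fast permutation machinery tests."""
    spec = SyntheticSpec(n_per_group=(12, 10), regions=regions6, n_blocks=2, seed=5)
    return generate_cohort(spec)


def random_graph(n, p, seed):
    """Seeded Erdos-Renyi adjacency as a plain boolean array."""
    rng = np.random.default_rng(seed)
    A = np.triu(rng.random((n, n)) < p, 1)
    return A | A.T


# named small graphs used across metric tests
def complete_graph(n):
    return ~np.eye(n, dtype=bool)


def star_graph(n_leaves):
    A = np.zeros((n_leaves + 1, n_leaves + 1), dtype=bool)
    A[0, 1:] = A[1:, 0] = True
    return A


def path_graph(n):
    A = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    A[idx, idx + 1] = A[idx + 1, idx] = True
    return A


def ring_lattice(n, k):
    """Ring of n nodes, each joined to its k nearest neighbours (k even)."""
    A = np.zeros((n, n), dtype=bool)
    for d in range(1, k // 2 + 1):
        i = np.arange(n)
        A[i, (i + d) % n] = True
        A[(i + d) % n, i] = True
    return A
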