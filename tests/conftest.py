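import numpy as np
import pytest

from richclubkit.core_network import BinaryNetwork, ConnectivityMatrix
from richclubkit.pipeline import RunConfig, run_analysis
from richclubkit.synthetic import SimulationConfig, generate_cohort


def labels(n):
    return tuple(f"R{i + 1:03d}" for i in range(n))


def binary_net(adj):
    adj = np.asarray(adj)
    return BinaryNetwork(labels(len(adj)), adj)


def weighted_net(weights, subject_id="s"):
    weights = np.asarray(weights)
    return ConnectivityMatrix(labels(len(weights)), weights, subject_id)


def random_binary_net(n, p, seed):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, 1)
    return binary_net((upper | upper.T).astype(int))


@pytest.fixture
def path4():
    a = np.zeros((4, 4), int)
    for i in range(3):
        a[i, i + 1] = a[i + 1, i] = 1
    return binary_net(a)


@pytest.fixture
def complete5():
    a = np.ones((5, 5), int) - np.eye(5, dtype=int)
    return binary_net(a)


@pytest.fixture
def star5():
    a = np.zeros((5, 5), int)
    a[0, 1:] = a[1:, 0] = 1
    return binary_net(a)


SMALL_COHORT_CONFIG = SimulationConfig(
    n_nodes=60,
    group_sizes={"MDD-CM": 12, "MDD-nCM": 10, "HC-CM": 10, "HC-nCM": 12},
    master_seed=424242,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort shared across pipeline tests."""
    return generate_cohort(SMALL_COHORT_CONFIG)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    mats, pheno = small_cohort
    config = RunConfig(n_random=30, n_perm=500, seed=7)
    return run_analysis(mats, pheno, config)
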