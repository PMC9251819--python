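import numpy as np
import pytest

from symptomnet import SimConfig, default_schema, make_ground_truth, sample_cohort
from symptomnet.synth import tiny_schema


@pytest.fixture(scope="session")
def schema43():
    return default_schema()


@pytest.fixture(scope="session")
def tiny6_schema():
    return tiny_schema(n_per_community=3, n_communities=2)


@pytest.fixture(scope="session")
def tiny6_cohort(tiny6_schema):
    """Small seeded cohort with one planted bridge, for fast pipeline tests."""
    cfg = SimConfig(
        n=300, seed=5, within_density=0.6, between_density=0.05, n_bridges=1
    )
    truth = make_ground_truth(tiny6_schema, cfg)
    return sample_cohort(truth, tiny6_schema, cfg), truth, cfg


@pytest.fixture(scope="session")
def default_cohort(schema43):
    cfg = SimConfig(seed=1)
    truth = make_ground_truth(schema43, cfg)
    return sample_cohort(truth, schema43, cfg), truth, cfg


def random_sparse_weights(p, rng, density=0.4):
    """Random symmetric partial-correlation-like matrix with zero diagonal."""
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(-0.5, 0.5)
    return w
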