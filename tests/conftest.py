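import numpy as np
import pytest

from nacmap import (
    Adjacency,
    CohortConfig,
    HubInjection,
    PipelineConfig,
    analyze_cohort,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_adjacency(rng, n, p=0.3):
    """Random undirected simple graph as an Adjacency."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    a = a + a.T
    return Adjacency(a=a)


@pytest.fixture(scope="session")
def small_config():
    """Small but structurally faithful cohort configuration."""
    return CohortConfig(
        n_controls=24,
        n_patients=3,
        n_regions=60,
        n_dmn=15,
        n_sessions=2,
        n_volumes=60,
        n_communities=3,
        hub_injection=HubInjection(n_hubs=3, hub_corr_boost=0.3),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    subjects, _, atlas = small_cohort
    return analyze_cohort(subjects, atlas, PipelineConfig())
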