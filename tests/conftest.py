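import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import commphen as cp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study bundle (seed 0)."""
    return cp.simulate_dataset(cp.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def relabund(dataset):
    return cp.normalize(dataset.counts)


@pytest.fixture(scope="session")
def profiler(dataset):
    return cp.CommunityPhenotypeProfiler(dataset.bpm, dataset.taxonomy).fit()


def random_composition(rng, n):
    p = rng.dirichlet(np.ones(n))
    return p / p.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """Tiny hand-written count table with depths bracketing the QC gate."""
    return pd.DataFrame(
        {
            "s_low": [2000, 1999, 1000],  # 4,999 reads
            "s_edge": [2000, 2000, 1000],  # 5,000 reads
            "s_high": [4000, 3000, 3000],  # 10,000 reads
        },
        index=["t1", "t2", "t3"],
    )
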