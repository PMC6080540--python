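import numpy as np
import pandas as pd
import pytest

from gutmwas.containers import CohortMetadata, RelAbundanceMatrix
from gutmwas.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with strong effects, reused by read-only tests."""
    return simulate_cohort(
        CohortConfig(seed=11, n_case=25, n_control=25, n_species=60,
                     n_diff_species=10, effect_size=8.0,
                     n_ko=120, n_modules=12, n_diff_modules=4)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_abundance(rng, n_features=8, n_samples=5, prefix="f"):
    raw = rng.random((n_features, n_samples))
    values = raw / raw.sum(axis=0)
    return RelAbundanceMatrix.from_arrays(
        values,
        [f"{prefix}{i}" for i in range(n_features)],
        [f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture
def metadata_two_groups():
    ids = [f"s{j}" for j in range(10)]
    return CohortMetadata(
        pd.DataFrame(
            {"group": ["case"] * 5 + ["control"] * 5,
             "stratum": ["postmenopausal"] * 10},
            index=pd.Index(ids, name="sample_id"),
        )
    )
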