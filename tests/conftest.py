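import numpy as np
import pytest

import hexcomb as hc


@pytest.fixture(scope="session")
def board():
    return hc.build_board("honeycomb97")


@pytest.fixture(scope="session")
def small_cohort():
    """Ten strong-preset games, validated, reused across test modules."""
    spec = hc.CohortSpec(n_groups=10, n_local=5, master_seed=42)
    return hc.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return hc.features_table(small_cohort)
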