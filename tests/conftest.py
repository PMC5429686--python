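import numpy as np
import pytest

import netstrat as ns


@pytest.fixture(scope="session")
def small_spec():
    """A fast 6-module cohort used by unit tests that only need structure."""
    return ns.SyntheticSpec(n_genes=300, n_modules=6, n_patients=60,
                            drivers_per_subtype=8, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return ns.generate(small_spec)


@pytest.fixture(scope="session")
def smoothed_small(small_cohort):
    restricted, _ = ns.intersect_with_network(small_cohort.mutation_matrix,
                                              small_cohort.network)
    return ns.smooth_cohort(restricted, small_cohort.network)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
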