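import warnings

import numpy as np
import pytest

from mothmass import (
    MothMassRegressor,
    SyntheticConfig,
    filter_records,
    load_reference_parameters,
    simulate_community,
)

# A small community for cheap unit tests: 3 families, 2 of them retained.
SMALL_CONFIG = SyntheticConfig(
    families=("Noctuidae", "Geometridae", "Sphingidae"),
    species_per_family=(8, 6, 2),
    n_individuals=150,
    n_sites=2,
    n_dates=4,
)


@pytest.fixture(scope="session")
def community():
    """Default-scale synthetic community (600 moths, 94 species, 11 families)."""
    records, guide, truth = simulate_community(SyntheticConfig(), seed=42)
    records, _ = filter_records(records)
    return records, guide, truth


@pytest.fixture(scope="session")
def small_community():
    records, guide, truth = simulate_community(SMALL_CONFIG, seed=7)
    records, _ = filter_records(records)
    return records, guide, truth


@pytest.fixture(scope="session")
def fitted(community):
    records, _, _ = community
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MothMassRegressor().fit(records)


@pytest.fixture(scope="session")
def reference_params():
    return load_reference_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
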