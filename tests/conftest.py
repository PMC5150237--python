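import numpy as np
import pytest

from mhcmate.indices import aa_distance_matrix
from mhcmate.simulate import (
    PreferenceSpec,
    default_config,
    generate_catalogs,
    generate_population,
    simulate_choices,
)


@pytest.fixture(scope="session")
def small_cfg():
    cfg = default_config(n_colonies=4, n_females=30, n_males=25, n_years=3)
    return cfg.with_genes("MHC1", "MHC2", "TAAR3", "MSAT1")


@pytest.fixture(scope="session")
def catalogs(small_cfg):
    return generate_catalogs(small_cfg, 11)


@pytest.fixture(scope="session")
def population(small_cfg, catalogs):
    return generate_population(small_cfg, catalogs, 12)


@pytest.fixture(scope="session")
def D1(catalogs):
    return aa_distance_matrix(catalogs["MHC1"])


@pytest.fixture(scope="session")
def events_null(population, D1):
    """133 choice events under uniform random choice (beta = 0)."""
    events, offspring = simulate_choices(
        population, PreferenceSpec("MALDiv", 0.0, "MHC1"), 133, 13, D=D1
    )
    return events, offspring


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
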