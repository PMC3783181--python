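import numpy as np
import pytest

from codonflux import (
    TRNAPool,
    TRNASpecies,
    WobbleRules,
    rate_table,
    toy_pool,
    toy_species,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20130710)


@pytest.fixture(scope="session")
def species():
    return toy_species()


@pytest.fixture(scope="session")
def pool():
    return toy_pool()


@pytest.fixture(scope="session")
def reference_rates():
    return rate_table(toy_pool(), toy_species())


def random_pool(rng, n_species, condition="rand"):
    """Random pool over random species (3-10 typical), for oracle checks."""
    from codonflux.fixtures import _random_species

    sp = _random_species(rng, n_species)
    conc = {s.name: float(rng.lognormal(np.log(80.0), 0.8)) for s in sp}
    return TRNAPool(condition=condition, concentration=conc), sp
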