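import numpy as np
import pytest

import phytofg as pf


@pytest.fixture(scope="session")
def catalog():
    return pf.load_catalog()


@pytest.fixture(scope="session")
def small_tables():
    """Hand-set 2-site x 4-month x 6-taxon fixture."""
    return pf.fixture_small()


@pytest.fixture(scope="session")
def small_biomass(small_tables, catalog):
    table, _ = small_tables
    return pf.compute_biomass(pf.classify_taxa(table, catalog))


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic study (5 sites x 48 months x 95 taxa)."""
    return pf.simulate(seed=20)


@pytest.fixture(scope="session")
def sim_biomass(sim_default):
    table, _, _ = sim_default
    return pf.compute_biomass(table)


def random_relative(rng, n):
    """Random relative-biomass vector (sums to 1)."""
    v = rng.dirichlet(np.ones(n))
    return v / v.sum()
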