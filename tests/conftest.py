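import numpy as np
import pandas as pd
import pytest

from eyevol.phylo import parse_newick, vcv_matrix
from eyevol.simulate import SimConfig, simulate_tree, simulate_traits
from eyevol.traits import add_log10, species_means

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return parse_newick(TOY_NEWICK)


@pytest.fixture
def toy_vcv(toy_tree):
    return vcv_matrix(toy_tree)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def sim_tree(sim_config):
    return simulate_tree(sim_config)


@pytest.fixture(scope="session")
def sim_records(sim_config, sim_tree):
    records, truth = simulate_traits(sim_tree, sim_config)
    return add_log10(records), truth


@pytest.fixture(scope="session")
def sim_means(sim_records):
    records, _ = sim_records
    return species_means(records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_tree(n, seed):
    """Small random tree helper for property-style tests."""
    return simulate_tree(SimConfig(seed=seed, n_species=n))
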