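import numpy as np
import pytest

from aacost.compendium import load_compendium
from aacost.properties import load_properties
from aacost.rates import RateMatrix, load_species_tree
from aacost.synth import default_toy_spec, make_toy_model


@pytest.fixture(scope="session")
def toy():
    """Toy model with analytic cost table."""
    model, analytic = make_toy_model(default_toy_spec())
    return model, analytic


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def analytic_costs(toy):
    return toy[1]


@pytest.fixture(scope="session")
def properties():
    return load_properties()


@pytest.fixture(scope="session")
def compendium_table():
    return load_compendium()


@pytest.fixture(scope="session")
def wag():
    return RateMatrix.wag()


@pytest.fixture(scope="session")
def null_matrix():
    return RateMatrix.null()


@pytest.fixture(scope="session")
def species_tree():
    return load_species_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
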