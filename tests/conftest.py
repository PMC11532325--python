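import numpy as np
import pytest
from hypothesis import settings

from steppesim.params import default_params, params_by_name
from steppesim.landscape import ArchetypeProfile, Landscape, load_archetypes
from steppesim.runner import run_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def pmap(params):
    return params_by_name(params)


@pytest.fixture(scope="session")
def archetypes():
    return load_archetypes()


@pytest.fixture(scope="session")
def experiment():
    """The full 5-landscape x 3-regime experiment at defaults, seed 0.

    Session-scoped: the 15 50-year runs are shared by the endpoint tests.
    """
    table, results = run_experiment(seed=0)
    return table, results


def make_landscape(pmap, entries, width=8, height=8, cell_size=10.0,
                   propagules=()):
    """Small landscape from (group, age, row, col, abundance) tuples."""
    ls = Landscape(width=width, height=height, cell_size=cell_size)
    for group, age, r, c, ab in entries:
        ls.add_abundance(group, age, (r, c), ab)
    for group, r, c, n in propagules:
        ls.propagules[group][r, c] = n
    return ls


@pytest.fixture
def small_landscape_factory(pmap):
    def factory(entries, **kw):
        return make_landscape(pmap, entries, **kw)
    return factory
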