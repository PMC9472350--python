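import pytest
from hypothesis import settings

from l1pattern import (
    ProbeDesignParams,
    design_probes,
    make_element_model,
    make_query_set,
    plant_elements,
    random_background,
)

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model():
    return make_element_model(seed=101)


@pytest.fixture(scope="session")
def query_set(model):
    return make_query_set(model, n_members=20, seed=202)


@pytest.fixture(scope="session")
def decoy():
    return random_background(120_000, seed=303, chrom="decoy")


@pytest.fixture(scope="session")
def probeset(model, query_set, decoy):
    return design_probes(query_set, decoy, ProbeDesignParams())


@pytest.fixture(scope="session")
def planted25(model):
    """Genome with 25 intact copies in 150 kb of background."""
    return plant_elements(150_000, model, 25, seed=404)


@pytest.fixture(scope="session")
def planted_mixed(model):
    """Genome mixing intact, 5'-truncated and internally deleted copies."""
    mix = {"intact": 0.5, "truncated_5p": 0.25, "internal_deletion": 0.25}
    return plant_elements(120_000, model, 20, mix, seed=606)


@pytest.fixture(scope="session")
def deletion_fixture(model):
    """One copy carrying the canonical 396-base internal deletion."""
    return plant_elements(20_000, model, 1, {"internal_deletion": 1.0}, seed=7)
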