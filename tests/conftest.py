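import pytest

from mirqc import litmine
from mirqc.simulate import SimulationParams, make_locus, simulate_reads


@pytest.fixture(scope="session")
def default_locus():
    return make_locus(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def family_table():
    return litmine.default_family_table()


@pytest.fixture(scope="session")
def species_lexicon():
    return litmine.default_species_lexicon()


@pytest.fixture(scope="session")
def positive_stems():
    return litmine.default_positive_stems()


@pytest.fixture(scope="session")
def negative_stems():
    return litmine.default_negative_stems()
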