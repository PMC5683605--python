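import pytest

from cpdpep import digestion, reference_data


@pytest.fixture(scope="session")
def precursors():
    return digestion.load_tryptic_precursors()


@pytest.fixture(scope="session")
def precursor_index(precursors):
    return {p.name: p.sequence for p in precursors}


@pytest.fixture(scope="session")
def tryptic_library(precursors):
    return digestion.build_library(precursors, max_missed=2)


@pytest.fixture(scope="session")
def tryptic_good_table():
    return reference_data.load_tryptic_good_substrates()


@pytest.fixture(scope="session")
def domain_table():
    return reference_data.load_tryptic_domain_substrates()


@pytest.fixture(scope="session")
def hek_good_table():
    return reference_data.load_hek_good_substrates()


@pytest.fixture(scope="session")
def kinetic_table():
    return reference_data.load_kinetic_constants()
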