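import pytest

from cdburden import (CpiTable, default_algorithm_config, default_ccs_mapping,
                      default_conditions)


@pytest.fixture(scope="session")
def config():
    return default_algorithm_config()


@pytest.fixture(scope="session")
def conditions():
    return default_conditions()


@pytest.fixture(scope="session")
def conditions_by_name(conditions):
    return {c.name: c for c in conditions}


@pytest.fixture(scope="session")
def ccs():
    return default_ccs_mapping()


@pytest.fixture(scope="session")
def cpi_identity():
    return CpiTable.identity()
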