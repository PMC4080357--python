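import pytest

import expanet as ex


@pytest.fixture(scope="session")
def toy_model():
    model = ex.toy_trn()
    ex.compile_model(model)
    return model


@pytest.fixture(scope="session")
def toy_universe(toy_model):
    return ex.compute_trn_expa_set(toy_model)


@pytest.fixture(scope="session")
def toy_expas(toy_universe):
    return toy_universe.as_expa_set()


@pytest.fixture(scope="session")
def fixture_nets():
    return ex.fixture_networks()
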