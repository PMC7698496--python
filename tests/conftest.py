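import pytest

from albolife import load_fixture


@pytest.fixture(scope="session")
def te_survival():
    return load_fixture("temperate", "stage_survival")


@pytest.fixture(scope="session")
def st_survival():
    return load_fixture("subtropical", "stage_survival")


@pytest.fixture(scope="session")
def te_durations():
    return load_fixture("temperate", "durations")


@pytest.fixture(scope="session")
def te_longevity():
    return load_fixture("temperate", "longevity")


@pytest.fixture(scope="session")
def te_gonotrophic():
    return load_fixture("temperate", "gonotrophic")
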