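import pytest
from hypothesis import settings

from mithrapbpk import get_physiology, load_compound

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mtm():
    return load_compound("MTM")


@pytest.fixture(scope="session")
def mtmsa():
    return load_compound("MTMSA-Trp")


@pytest.fixture(scope="session")
def mouse():
    return get_physiology("mouse")


@pytest.fixture(scope="session")
def human():
    return get_physiology("human")


@pytest.fixture(scope="session")
def monkey():
    return get_physiology("monkey")
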