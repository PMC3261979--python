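import pytest

from mixkin import build_btex_model


@pytest.fixture(scope="session")
def benzene_model():
    """Single-chemical type I benzene model at calibrated posterior modes."""
    return build_btex_model(("benzene",))


@pytest.fixture(scope="session")
def btex_model():
    """Quaternary type I BTEX model at calibrated posterior modes."""
    return build_btex_model()
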