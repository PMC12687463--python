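import pytest

from hepgck import KineticParameters, baseline_scenario


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def baseline(params):
    return baseline_scenario(params)
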