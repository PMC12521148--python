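import pytest

from asthmaecon import UtilityModel, WTPThreshold, datasets


@pytest.fixture(scope="session")
def utility_model():
    return UtilityModel()


@pytest.fixture(scope="session")
def wtp():
    return WTPThreshold()


@pytest.fixture(scope="session")
def ics_strategies():
    return datasets.study_strategies("ics")


@pytest.fixture(scope="session")
def medication_strategies():
    return datasets.study_strategies("medication")
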