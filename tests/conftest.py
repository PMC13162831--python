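import pytest

from mycorefinery import datasets


@pytest.fixture(scope="session")
def study_profile():
    """The packaged GC-MS FAME composition (15 esters)."""
    return datasets.load_fame_profile()


@pytest.fixture(scope="session")
def substrate_series():
    return datasets.load_substrate_series()


@pytest.fixture(scope="session")
def pretreatment_obs():
    return datasets.load_pretreatment_observations()


@pytest.fixture(scope="session")
def dose_response():
    return datasets.load_pigment_dose_response()
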