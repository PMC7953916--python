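import pytest
from hypothesis import settings

from regenscore import datasets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cropland_matrix():
    return datasets.load_cropland_matrix()


@pytest.fixture(scope="session")
def rangeland_matrix():
    return datasets.load_rangeland_matrix()


@pytest.fixture(scope="session")
def cropland_profiles():
    return datasets.cropland_profiles()


@pytest.fixture(scope="session")
def rangeland_profiles():
    return datasets.rangeland_profiles()
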