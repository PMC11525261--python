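import pytest

from stimtime.core import DetectionParams, load_packaged_profile


@pytest.fixture(scope="session")
def xiaomi():
    return load_packaged_profile("xiaomi_mi_a2")


@pytest.fixture(scope="session")
def samsung():
    return load_packaged_profile("samsung_a40")


@pytest.fixture()
def params():
    return DetectionParams()
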