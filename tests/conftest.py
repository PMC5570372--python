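import pytest
from hypothesis import settings as hsettings

from thyroquant.registry import AcquisitionSettings, default_registry

hsettings.register_profile("repro", derandomize=True, deadline=None)
hsettings.load_profile("repro")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def settings():
    return AcquisitionSettings()
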