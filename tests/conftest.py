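import pytest

from dfiscreen.fragments import build_registry
from dfiscreen.screen import ScreenParams


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def params():
    return ScreenParams()
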