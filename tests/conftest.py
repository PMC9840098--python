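import pytest

from pddi import crypto as C
from pddi.synthdata import build_linked_pair, preset_spec
from pddi.synthdata.lexicons import load_default_lexicons


@pytest.fixture(scope="session")
def tiny_params():
    return C.tiny_params()


@pytest.fixture(scope="session")
def test_params():
    return C.test_params()


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


@pytest.fixture(scope="session")
def small_colorectal_pair():
    """Colorectal study condition scaled down in size (plan untouched)."""
    return build_linked_pair(preset_spec("colorectal", seed=11, scale=0.05))


@pytest.fixture(scope="session")
def small_breast_pair():
    return build_linked_pair(preset_spec("breast", seed=11, scale=0.05))
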