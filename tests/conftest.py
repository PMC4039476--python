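import pytest

import symmatch as sm


@pytest.fixture
def reg_x():
    return sm.make_registry([("X", False)])


@pytest.fixture
def reg_s():
    return sm.make_registry([("S", True)])
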