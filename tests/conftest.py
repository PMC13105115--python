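import pytest

from landfillch4 import load_fixtures


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()
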