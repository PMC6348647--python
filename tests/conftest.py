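import pytest

from fluxcheck.fixtures import toy_models


@pytest.fixture(scope="session")
def toys():
    return toy_models()
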