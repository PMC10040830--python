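import pytest

from indolepath.network import build_default_network
from indolepath.synthetic import synthetic_reference_db


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def refdb():
    return synthetic_reference_db()
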