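import pytest

from lavermux import bundled_panel, bundled_products
from lavermux.fixtures import build_reference_set


@pytest.fixture(scope="session")
def panel():
    return bundled_panel()


@pytest.fixture(scope="session")
def products():
    return bundled_products()


@pytest.fixture(scope="session")
def reference_set(panel):
    return build_reference_set(panel, seed=0)
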