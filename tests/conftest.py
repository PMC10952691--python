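import pytest

from thiotraits.catalog import load_default_catalog, load_published_calls


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def published_calls():
    return load_published_calls()
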