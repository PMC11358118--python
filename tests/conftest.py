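import pytest

from picomine import default_registry, extended_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def schema(registry):
    return registry.tag_schema()


@pytest.fixture(scope="session")
def ext_registry():
    return extended_registry()
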