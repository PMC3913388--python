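import pytest

from glucosim.config import load_config


@pytest.fixture(scope="session")
def config():
    """Default simulator configuration shared across the suite."""
    return load_config()


@pytest.fixture(scope="session")
def tables(config):
    """The nine-member lookup-table set (built once; ~1 s)."""
    return config.tables()


@pytest.fixture(scope="session")
def constants(config):
    return config.constants
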