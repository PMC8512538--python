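import pytest

from bibrank import generate
from bibrank.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def default_world():
    """Default 4-cluster, 200-document synthetic corpus with topics/qrels."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_corpus(default_world):
    return default_world[0]


@pytest.fixture(scope="session")
def default_topics(default_world):
    return default_world[1]


@pytest.fixture(scope="session")
def default_qrels(default_world):
    return default_world[2]
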