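import pytest

from biotagger.config import ServiceConfig
from biotagger.fixtures import FixtureSpec, make_corpus, make_dictionary


@pytest.fixture(scope="session")
def seed7_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def seed7_dictionary(seed7_spec):
    return make_dictionary(seed7_spec)


@pytest.fixture(scope="session")
def seed7_corpus(seed7_spec, seed7_dictionary):
    return make_corpus(seed7_spec, seed7_dictionary)


@pytest.fixture()
def fast_config():
    """Server config suitable for tests: ephemeral port, snappy retries."""
    return ServiceConfig(port=0, deliver_backoff=0.05, fetch_timeout=5.0)


def make_tiny_dictionary():
    """The two-entity lexicon used in doc examples: aspirin + a gene."""
    from biotagger.dictionary import load_dictionary

    entities = ["1\t-1\tCID000002244", "2\t9606\t9606.ENSP00000269305"]
    names = ["1\taspirin", "2\tp53", "2\tTP53"]
    return load_dictionary(entities, names)
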