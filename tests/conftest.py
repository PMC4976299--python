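import pytest

from dislex.normalize import DictionaryIndex
from dislex.synth import FixtureSpec, generate_corpus, generate_dictionary


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, n_docs=20)


@pytest.fixture(scope="session")
def resources(small_spec):
    return generate_dictionary(small_spec)


@pytest.fixture(scope="session")
def corpus(small_spec, resources):
    return generate_corpus(small_spec, resources)


@pytest.fixture(scope="session")
def index(resources) -> DictionaryIndex:
    return DictionaryIndex(resources.dictionary)
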