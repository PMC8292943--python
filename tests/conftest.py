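import pytest

from hitmap import CategoryScheme, GeneratorConfig, generate_corpus, \
    make_fixture_tree
from hitmap.synthetic_examples import worked_example_tree


@pytest.fixture(scope="session")
def fixture_tree():
    """Deterministic synthetic vocabulary covering all category branches."""
    return make_fixture_tree(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def example_tree():
    """Vocabulary subset backing the two worked scoring examples."""
    return worked_example_tree()


@pytest.fixture(scope="session")
def scheme():
    return CategoryScheme()


@pytest.fixture(scope="session")
def small_corpus(fixture_tree):
    """200 synthetic articles plus their ground-truth category counts."""
    config = GeneratorConfig(n_articles=200, seed=7)
    return generate_corpus(config, fixture_tree)
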