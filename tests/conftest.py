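import pytest

from manguare.datasets import synthetic_name_lexicon
from manguare.synth import generate_drummed_corpus, generate_lexicon


@pytest.fixture(scope="session")
def small_corpus():
    """A modest synthetic drummed corpus (~3,000 intra-word IBDs)."""
    medial = generate_lexicon(40, seed=11, position="medial")
    final = generate_lexicon(12, seed=12, position="final")
    return generate_drummed_corpus(
        {"medial": medial, "final": final}, n_messages=110, seed=13
    )


@pytest.fixture(scope="session")
def small_corpus_frame(small_corpus):
    return small_corpus.frame()


@pytest.fixture(scope="session")
def name_words():
    return synthetic_name_lexicon()
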