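import random

import pytest

from icdcoder import (
    CooccurrenceConfig,
    ExactMatchBackend,
    GreedyTokenizer,
    IdfModel,
    KnowledgeBackend,
    LcsBackend,
    SimilarityConfig,
    VectorBackend,
    build_code_system,
    build_cooccurrence,
)
from icdcoder.synthetic import (
    FixtureSpec,
    gen_code_system,
    gen_corpus,
    gen_queries,
    gen_sememe_taxonomy,
)


@pytest.fixture(scope="session")
def default_fixture():
    return gen_code_system(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def default_system(default_fixture):
    return build_code_system(default_fixture.entries, default_fixture.sections)


@pytest.fixture(scope="session")
def default_tokenizer(default_fixture):
    return GreedyTokenizer(default_fixture.lexicon)


@pytest.fixture
def lcs_config(default_tokenizer):
    return SimilarityConfig(LcsBackend(), IdfModel.uniform(), tokenizer=default_tokenizer)


def make_all_backends(fixture, seed=0, n_docs=60, doc_length=25, coverage=0.9):
    """The four word-similarity backends wired to one synthetic study."""
    corpus = gen_corpus(fixture, n_docs=n_docs, doc_length=doc_length, seed=seed)
    model = build_cooccurrence(corpus, CooccurrenceConfig.word_default())
    tax = gen_sememe_taxonomy(fixture, seed=seed, coverage=coverage)
    return {
        "exact": ExactMatchBackend(),
        "lcs": LcsBackend(),
        "knowledge": KnowledgeBackend(tax),
        "vector": VectorBackend(model),
    }


def random_cjk_word(rng: random.Random, lo=1, hi=5) -> str:
    return "".join(
        chr(0x4E00 + rng.randrange(80)) for _ in range(rng.randint(lo, hi))
    )
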