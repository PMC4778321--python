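"""Word-similarity backends against independent oracles and their invariants."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from icdcoder import (
    CooccurrenceConfig,
    SememeTaxonomy,
    TaxonomyParams,
    build_cooccurrence,
    exact_match_similarity,
    knowledge_similarity,
    lcs_similarity,
    sememe_similarity,
    vector_similarity,
)
from icdcoder.word_similarity import CooccurrenceModel, lcs_length

words = st.text(
    alphabet=st.characters(min_codepoint=0x4E00, max_codepoint=0x4E30),
    min_size=1,
    max_size=6,
)


# ---------------------------------------------------------------------------
# string similarity
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "w1, w2, expected",
    [
        ("伤寒", "伤寒", 1.0),
        ("AB", "CD", 0.0),
        ("ABCD", "ACD", 0.75),  # |LCS|=3 -> 3/(4+3-3)
    ],
)
def test_lcs_similarity_examples(w1, w2, expected):
    assert lcs_similarity(w1, w2) == pytest.approx(expected)


def test_lcs_rejects_empty_words():
    with pytest.raises(ValueError):
        lcs_similarity("", "AB")


def test_lcs_against_memoized_recursion_oracle():
    rng = random.Random(17)
    alphabet = [chr(0x4E00 + i) for i in range(12)] + list("ABCDE")
    for _ in range(300):
        a = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 7)))
        b = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 7)))
        assert lcs_length(a, b) == _oracles.lcs_len_oracle(a, b)
        assert lcs_similarity(a, b) == pytest.approx(_oracles.lcs_sim_oracle(a, b))


@given(words, words)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_string_backends_symmetric_and_bounded(w1, w2):
    for fn in (lcs_similarity, exact_match_similarity):
        s = fn(w1, w2)
        assert 0.0 <= s <= 1.0
        assert s == fn(w2, w1)
    # the equality indicator never exceeds LCS similarity, and both hit 1
    # exactly on identical strings
    assert exact_match_similarity(w1, w2) <= lcs_similarity(w1, w2)
    assert (lcs_similarity(w1, w2) == 1.0) == (w1 == w2)


def test_exact_match_equals_lcs_equal_to_one_indicator():
    rng = random.Random(3)
    pool = [chr(0x4E00 + i) for i in range(6)]
    for _ in range(200):
        a = "".join(rng.choice(pool) for _ in range(rng.randint(1, 4)))
        b = "".join(rng.choice(pool) for _ in range(rng.randint(1, 4)))
        assert exact_match_similarity(a, b) == float(lcs_similarity(a, b) == 1.0)


# ---------------------------------------------------------------------------
# sememe taxonomy
# ---------------------------------------------------------------------------
@pytest.fixture
def toy_taxonomy():
    #        root
    #       /    \
    #      n1     n2
    #     /  \      \
    #    s1  s2     s3
    edges = [("n1", "root"), ("n2", "root"), ("s1", "n1"), ("s2", "n1"), ("s3", "n2")]
    lexicon = {
        "甲": [["s1"]],
        "乙": [["s2"], ["s3", "s1"]],
        "丙": [["s3"]],
    }
    return edges, SememeTaxonomy.from_edges(edges, lexicon)


def test_sememe_similarity_examples(toy_taxonomy):
    _, tax = toy_taxonomy
    assert sememe_similarity("s1", "s1", TaxonomyParams(1.6), tax) == 1.0
    # distance(s1, s2) = 2 via n1; the alpha = distance point gives one half
    assert sememe_similarity("s1", "s2", TaxonomyParams(2.0), tax) == pytest.approx(0.5)
    assert sememe_similarity("s1", "s2", TaxonomyParams(1.6), tax) == pytest.approx(1.6 / 3.6)


def test_sememe_distances_match_bfs_oracle(toy_taxonomy):
    edges, tax = toy_taxonomy
    nodes = ["root", "n1", "n2", "s1", "s2", "s3"]
    for a in nodes:
        for b in nodes:
            assert tax.distance(a, b) == _oracles.bfs_distance(edges, a, b)


def test_sememe_similarity_monotone_in_distance_and_alpha(toy_taxonomy):
    _, tax = toy_taxonomy
    alpha = TaxonomyParams(1.6)
    d_chain = [("s1", "s1"), ("s1", "s2"), ("s1", "s3")]  # distances 0, 2, 4
    sims = [sememe_similarity(a, b, alpha, tax) for a, b in d_chain]
    assert sims[0] > sims[1] > sims[2]
    # alpha -> infinity pushes any fixed pair toward 1
    assert sememe_similarity("s1", "s3", TaxonomyParams(1e9), tax) == pytest.approx(1.0, abs=1e-8)


def test_unknown_sememe_raises(toy_taxonomy):
    _, tax = toy_taxonomy
    with pytest.raises(KeyError):
        tax.distance("s1", "missing")


def test_cycle_rejected():
    with pytest.raises(ValueError):
        SememeTaxonomy.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


def test_knowledge_similarity_fallback_and_enumeration(toy_taxonomy):
    _, tax = toy_taxonomy
    alpha = TaxonomyParams(1.6)
    # vocational words outside the lexicon fall back to string similarity
    assert knowledge_similarity("木糖葡萄球菌", "木糖葡萄球菌", tax, alpha) == 1.0
    assert knowledge_similarity("木糖葡萄球菌", "甲", tax, alpha) == lcs_similarity(
        "木糖葡萄球菌", "甲"
    )
    # in-lexicon identical word
    assert knowledge_similarity("甲", "甲", tax, alpha) == 1.0
    # 2-concept vs 1-concept: brute-force max over all concept pairs of the
    # primary-sememe similarity, with BFS distances
    edges = [("n1", "root"), ("n2", "root"), ("s1", "n1"), ("s2", "n1"), ("s3", "n2")]
    expected = max(
        alpha.alpha / (_oracles.bfs_distance(edges, c1[0], c2[0]) + alpha.alpha)
        for c1 in [("s2",), ("s3", "s1")]
        for c2 in [("s1",)]
    )
    assert knowledge_similarity("乙", "甲", tax, alpha) == pytest.approx(expected)


def test_taxonomy_file_round_trip(tmp_path, toy_taxonomy):
    _, tax = toy_taxonomy
    tax.save(tmp_path / "edges.tsv", tmp_path / "lex.tsv")
    clone = SememeTaxonomy.from_files(tmp_path / "edges.tsv", tmp_path / "lex.tsv")
    assert set(clone.graph.nodes) == set(tax.graph.nodes)
    assert clone.lexicon == tax.lexicon
    for a in ("s1", "s2", "s3"):
        for b in ("s1", "s2", "s3"):
            assert clone.distance(a, b) == tax.distance(a, b)


# ---------------------------------------------------------------------------
# co-occurrence vectors
# ---------------------------------------------------------------------------
def _counts_as_dict(model):
    coo = model.counts.tocoo()
    inv_v = {i: w for w, i in model.vocab.items()}
    inv_d = {j: u for u, j in model.dims.items()}
    return {(inv_v[i], inv_d[j]): int(v) for i, j, v in zip(coo.row, coo.col, coo.data)}


def test_single_word_document_has_no_context():
    model = build_cooccurrence([["孤"]], CooccurrenceConfig(mode="word_dims", window=3))
    assert model.counts.sum() == 0
    assert np.all(model.vector("孤") == 0)


def test_three_word_window_one_counts():
    model = build_cooccurrence([["a", "b", "c"]], CooccurrenceConfig(mode="word_dims", window=1))
    counts = _counts_as_dict(model)
    assert counts.get(("b", "a"), 0) == 1
    assert counts.get(("b", "c"), 0) == 1
    assert counts.get(("a", "b"), 0) == 1
    assert counts.get(("a", "c"), 0) == 0


@pytest.mark.parametrize("mode", ["word_dims", "char_dims"])
@pytest.mark.parametrize("window", [1, 3, 7])
def test_cooccurrence_matches_naive_oracle(mode, window):
    rng = random.Random(100 + window)
    pool = [chr(0x4E00 + i) for i in range(15)]
    docs = [
        ["".join(rng.choice(pool) for _ in range(rng.randint(1, 3))) for _ in range(30)]
        for _ in range(20)
    ]
    model = build_cooccurrence(docs, CooccurrenceConfig(mode=mode, window=window))
    assert _counts_as_dict(model) == dict(
        _oracles.naive_cooccurrence(docs, mode, window)
    )


def test_preprocessing_drops_numerals_punctuation_stopwords():
    docs = [["甲", "3", "，", "的", "乙"]]
    cfg = CooccurrenceConfig(mode="word_dims", window=1, stopwords=frozenset({"的"}))
    model = build_cooccurrence(docs, cfg)
    # after removal the content sequence is 甲 乙: adjacent within window 1
    assert set(model.vocab) == {"甲", "乙"}
    assert _counts_as_dict(model) == {("甲", "乙"): 1, ("乙", "甲"): 1}


def test_vector_similarity_closed_forms():
    vocab = {"u": 0, "v": 1, "w": 2}
    dims = {"a": 0, "b": 1, "c": 2}
    from scipy import sparse

    counts = sparse.csr_matrix(np.array([[1, 1, 0], [1, 0, 0], [1, 1, 0]]))
    model = CooccurrenceModel(vocab, dims, counts)
    assert vector_similarity("u", "w", model) == pytest.approx(1.0)  # identical vectors
    assert vector_similarity("u", "v", model) == pytest.approx(1 / math.sqrt(2))
    assert vector_similarity("u", "缺", model) == 0.0  # absent word: zero vector


def test_orthogonal_context_vectors_score_zero():
    model = build_cooccurrence(
        [["甲", "乙"], ["丙", "丁"]], CooccurrenceConfig(mode="word_dims", window=1)
    )
    assert vector_similarity("甲", "丙", model) == 0.0
    assert vector_similarity("甲", "甲", model) == pytest.approx(1.0)


def test_cooccurrence_model_file_round_trip(tmp_path):
    docs = [["甲", "乙", "丙"], ["乙", "丙", "丁"]]
    model = build_cooccurrence(docs, CooccurrenceConfig(mode="char_dims", window=2))
    model.save(tmp_path / "vectors")
    clone = CooccurrenceModel.load(tmp_path / "vectors")
    assert clone.vocab == model.vocab
    assert clone.dims == model.dims
    assert (clone.counts != model.counts).nnz == 0
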