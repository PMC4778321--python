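"""Word-to-word similarity backends.

Four interchangeable backends map a word pair into [0, 1]:

* ``ExactMatchBackend`` — the string-equality indicator (the no-semantics
  baseline).
* ``LcsBackend`` — character-level longest-common-subsequence similarity
  ``len(LCS) / (len(w1) + len(w2) - len(LCS))``.
* ``KnowledgeBackend`` — sememe-taxonomy similarity in the style of the
  classic HowNet-based measure: a word maps to concepts, a concept to an
  ordered sememe list, and sememe similarity is ``alpha / (d + alpha)`` with
  ``d`` the shortest-path distance in the sememe tree.  Word pairs outside
  the lexicon fall back to LCS similarity.
* ``VectorBackend`` — cosine similarity of co-occurrence count vectors whose
  context dimensions are either content words (window 3 per side) or content
  characters (window 7 per side).

All backends memoize pair scores (symmetric), since encoding evaluates the
same pairs against many candidate codes.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

from .tokenizers import TokenizedText, content_chars, is_content_token

__all__ = [
    "WordSimilarityBackend",
    "ExactMatchBackend",
    "LcsBackend",
    "KnowledgeBackend",
    "VectorBackend",
    "SememeTaxonomy",
    "TaxonomyParams",
    "CooccurrenceConfig",
    "CooccurrenceModel",
    "lcs_length",
    "lcs_similarity",
    "exact_match_similarity",
    "sememe_similarity",
    "knowledge_similarity",
    "build_cooccurrence",
    "vector_similarity",
]


# ---------------------------------------------------------------------------
# backend contract
# ---------------------------------------------------------------------------
class WordSimilarityBackend(ABC):
    """Contract: ``similarity(w1, w2)`` in [0, 1], symmetric."""

    name: str = "abstract"

    def __init__(self) -> None:
        self._cache: dict[tuple[str, str], float] = {}

    def similarity(self, w1: str, w2: str) -> float:
        key = (w1, w2) if w1 <= w2 else (w2, w1)
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = float(self._score(*key))
        return hit

    __call__ = similarity

    @abstractmethod
    def _score(self, w1: str, w2: str) -> float: ...


# ---------------------------------------------------------------------------
# string backends
# ---------------------------------------------------------------------------
def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence (character level)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def lcs_similarity(w1: str, w2: str) -> float:
    """``len(LCS) / (len(w1) + len(w2) - len(LCS))``; symmetric, in [0, 1]."""
    if not w1 or not w2:
        raise ValueError("lcs_similarity requires non-empty words")
    l = lcs_length(w1, w2)
    return l / (len(w1) + len(w2) - l)


def exact_match_similarity(w1: str, w2: str) -> float:
    """1.0 iff the strings are equal, else 0.0."""
    return 1.0 if w1 == w2 else 0.0


class ExactMatchBackend(WordSimilarityBackend):
    name = "exact"

    def _score(self, w1: str, w2: str) -> float:
        return exact_match_similarity(w1, w2)


class LcsBackend(WordSimilarityBackend):
    name = "lcs"

    def _score(self, w1: str, w2: str) -> float:
        return lcs_similarity(w1, w2)


# ---------------------------------------------------------------------------
# knowledge (sememe taxonomy) backend
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TaxonomyParams:
    """``alpha`` controls how fast sememe similarity decays with tree distance."""

    alpha: float = 1.6

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


Concept = tuple[str, ...]  # an ordered, non-empty sememe list


@dataclass
class SememeTaxonomy:
    """A rooted sememe tree (or forest) plus a word -> concepts lexicon."""

    graph: nx.Graph
    lexicon: dict[str, tuple[Concept, ...]]

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() and not nx.is_forest(self.graph):
            raise ValueError("sememe edges contain a cycle")
        for word, concepts in self.lexicon.items():
            for concept in concepts:
                if not concept:
                    raise ValueError(f"word {word!r} has an empty concept")
                for s in concept:
                    if s not in self.graph:
                        raise ValueError(
                            f"sememe {s!r} (word {word!r}) missing from taxonomy"
                        )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        lexicon: dict[str, Sequence[Sequence[str]]] | None = None,
    ) -> "SememeTaxonomy":
        g = nx.Graph()
        for child, parent in edges:
            g.add_edge(child, parent)
        lex = {
            w: tuple(tuple(c) for c in cs) for w, cs in (lexicon or {}).items()
        }
        return cls(g, lex)

    def distance(self, s1: str, s2: str) -> float:
        """Shortest undirected path length in edges; inf across components."""
        if s1 not in self.graph or s2 not in self.graph:
            missing = s1 if s1 not in self.graph else s2
            raise KeyError(f"sememe {missing!r} not in taxonomy")
        if s1 == s2:
            return 0.0
        try:
            return float(nx.shortest_path_length(self.graph, s1, s2))
        except nx.NetworkXNoPath:
            return float("inf")

    # -- file I/O ---------------------------------------------------------
    @classmethod
    def from_files(cls, edges_path: str | Path, lexicon_path: str | Path | None = None):
        """Edges TSV: ``child<TAB>parent``; lexicon TSV:
        ``word<TAB>concept_id<TAB>sememe1,sememe2,...``.

        This schema is the documented target for converters from a HowNet
        export (one row per word sense; sememes in definition order); no
        knowledge-base data ships with the package.
        """
        edges = []
        for line in Path(edges_path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")
            edges.append((child, parent))
        lex: dict[str, list[tuple[str, ...]]] = {}
        if lexicon_path is not None:
            for line in Path(lexicon_path).read_text(encoding="utf-8").splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                word, _concept_id, sememes = line.split("\t")
                lex.setdefault(word, []).append(tuple(sememes.split(",")))
        return cls.from_edges(edges, {w: tuple(cs) for w, cs in lex.items()})

    def save(self, edges_path: str | Path, lexicon_path: str | Path) -> None:
        tree = nx.bfs_tree(self.graph, next(iter(sorted(self.graph)))) if self.graph else None
        lines = []
        if tree is not None:
            for parent, child in sorted(tree.edges()):
                lines.append(f"{child}\t{parent}")
        Path(edges_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
        rows = []
        for word in sorted(self.lexicon):
            for k, concept in enumerate(self.lexicon[word]):
                rows.append(f"{word}\tc{k}\t{','.join(concept)}")
        Path(lexicon_path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def sememe_similarity(
    s1: str, s2: str, params: TaxonomyParams, tax: SememeTaxonomy
) -> float:
    """``alpha / (distance(s1, s2) + alpha)``; 1 at distance 0, -> 0 as d -> inf."""
    d = tax.distance(s1, s2)
    if d == float("inf"):
        return 0.0
    return params.alpha / (d + params.alpha)


def _concept_similarity(
    c1: Concept,
    c2: Concept,
    params: TaxonomyParams,
    tax: SememeTaxonomy,
    strategy: Literal["primary", "greedy_average"],
) -> float:
    if strategy == "primary":
        return sememe_similarity(c1[0], c2[0], params, tax)
    # greedy best-pair matching over the full sememe lists, averaged
    left, right = list(c1), list(c2)
    sims = []
    while left and right:
        best = max(
            ((sememe_similarity(a, b, params, tax), a, b) for a in left for b in right),
            key=lambda t: t[0],
        )
        sims.append(best[0])
        left.remove(best[1])
        right.remove(best[2])
    return sum(sims) / len(sims)


def knowledge_similarity(
    w1: str,
    w2: str,
    tax: SememeTaxonomy,
    params: TaxonomyParams = TaxonomyParams(),
    strategy: Literal["primary", "greedy_average"] = "primary",
) -> float:
    """Max concept-pair similarity; LCS fallback when a word is out of lexicon."""
    cs1, cs2 = tax.lexicon.get(w1), tax.lexicon.get(w2)
    if not cs1 or not cs2:
        return lcs_similarity(w1, w2)
    return max(
        _concept_similarity(c1, c2, params, tax, strategy) for c1 in cs1 for c2 in cs2
    )


class KnowledgeBackend(WordSimilarityBackend):
    name = "knowledge"

    def __init__(
        self,
        tax: SememeTaxonomy,
        params: TaxonomyParams = TaxonomyParams(),
        strategy: Literal["primary", "greedy_average"] = "primary",
    ):
        super().__init__()
        self.tax = tax
        self.params = params
        self.strategy = strategy

    def _score(self, w1: str, w2: str) -> float:
        return knowledge_similarity(w1, w2, self.tax, self.params, self.strategy)


# ---------------------------------------------------------------------------
# distributional (context-vector) backend
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CooccurrenceConfig:
    """Context-vector construction parameters.

    ``mode="word_dims"`` counts content words within ``window`` content words
    per side (default window 3); ``mode="char_dims"`` counts content
    characters within ``window`` content characters per side (default 7),
    excluding the target occurrence's own characters.  Stop words, numerals
    and punctuation are removed before windows are measured.
    """

    mode: Literal["word_dims", "char_dims"] = "word_dims"
    window: int = 3
    stopwords: frozenset[str] = frozenset()
    per_side: bool = True  # window counts units per side (symmetric context)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @classmethod
    def word_default(cls, stopwords: frozenset[str] = frozenset()):
        return cls(mode="word_dims", window=3, stopwords=stopwords)

    @classmethod
    def char_default(cls, stopwords: frozenset[str] = frozenset()):
        return cls(mode="char_dims", window=7, stopwords=stopwords)


@dataclass
class CooccurrenceModel:
    """Vocabulary, context-dimension index, and the sparse count matrix."""

    vocab: dict[str, int]
    dims: dict[str, int]
    counts: sparse.csr_matrix

    def vector(self, word: str) -> np.ndarray:
        """Dense context vector; all-zero for words absent from the corpus."""
        i = self.vocab.get(word)
        if i is None:
            return np.zeros(len(self.dims))
        return np.asarray(self.counts[i].todense()).ravel()

    # -- file I/O: triplets plus index files ------------------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        inv_v = sorted(self.vocab, key=self.vocab.get)
        inv_d = sorted(self.dims, key=self.dims.get)
        prefix.with_suffix(".vocab.tsv").write_text(
            "\n".join(inv_v) + "\n", encoding="utf-8"
        )
        prefix.with_suffix(".dims.tsv").write_text(
            "\n".join(inv_d) + "\n", encoding="utf-8"
        )
        coo = self.counts.tocoo()
        rows = [
            f"{inv_v[i]}\t{inv_d[j]}\t{int(v)}"
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ]
        prefix.with_suffix(".counts.tsv").write_text(
            "\n".join(rows) + ("\n" if rows else ""), encoding="utf-8"
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "CooccurrenceModel":
        prefix = Path(prefix)
        inv_v = prefix.with_suffix(".vocab.tsv").read_text(encoding="utf-8").splitlines()
        inv_d = prefix.with_suffix(".dims.tsv").read_text(encoding="utf-8").splitlines()
        vocab = {w: i for i, w in enumerate(inv_v)}
        dims = {u: j for j, u in enumerate(inv_d)}
        mat = sparse.dok_matrix((len(vocab), len(dims)), dtype=np.int64)
        for line in prefix.with_suffix(".counts.tsv").read_text(encoding="utf-8").splitlines():
            w, u, c = line.split("\t")
            mat[vocab[w], dims[u]] = int(c)
        return cls(vocab, dims, mat.tocsr())


def _content_tokens(doc: TokenizedText | Sequence[str], stopwords: frozenset[str]):
    tokens = doc.tokens if isinstance(doc, TokenizedText) else tuple(doc)
    return [t for t in tokens if is_content_token(t, stopwords)]


def build_cooccurrence(
    corpus: Sequence[TokenizedText | Sequence[str]], config: CooccurrenceConfig
) -> CooccurrenceModel:
    """Count context co-occurrences over a tokenized corpus.

    Preprocessing (stop word / numeral / punctuation removal) happens here;
    windows are measured on the collapsed content sequence.
    """
    docs = [_content_tokens(doc, config.stopwords) for doc in corpus]
    vocab = {w: i for i, w in enumerate(sorted({w for d in docs for w in d}))}
    if config.mode == "word_dims":
        dims = dict(vocab)
    else:
        dims = {
            ch: j
            for j, ch in enumerate(
                sorted({c for d in docs for w in d for c in content_chars(w)})
            )
        }
    counts: dict[tuple[int, int], int] = {}
    win = config.window
    for doc in docs:
        if config.mode == "word_dims":
            for i, w in enumerate(doc):
                lo = max(0, i - win)
                hi = min(len(doc), i + win + 1) if config.per_side else min(
                    len(doc), i + 1
                )
                row = vocab[w]
                for j in range(lo, hi):
                    if j == i:
                        continue
                    key = (row, dims[doc[j]])
                    counts[key] = counts.get(key, 0) + 1
        else:
            # character stream of the content tokens, with each token's span
            stream: list[str] = []
            spans: list[tuple[int, int]] = []
            for w in doc:
                cs = content_chars(w)
                spans.append((len(stream), len(stream) + len(cs)))
                stream.extend(cs)
            for w, (a, b) in zip(doc, spans):
                row = vocab[w]
                context = stream[max(0, a - win) : a] + stream[b : b + win]
                for ch in context:
                    key = (row, dims[ch])
                    counts[key] = counts.get(key, 0) + 1
    if counts:
        rows, cols = zip(*counts)
        mat = sparse.coo_matrix(
            (list(counts.values()), (rows, cols)),
            shape=(len(vocab), len(dims)),
            dtype=np.int64,
        ).tocsr()
    else:
        mat = sparse.csr_matrix((len(vocab), len(dims)), dtype=np.int64)
    return CooccurrenceModel(vocab, dims, mat)


def vector_similarity(w1: str, w2: str, model: CooccurrenceModel) -> float:
    """Cosine of the two context vectors; 0 if either has no evidence."""
    v1, v2 = model.vector(w1), model.vector(w2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    return float(np.clip(v1 @ v2 / (n1 * n2), 0.0, 1.0))


class VectorBackend(WordSimilarityBackend):
    name = "vector"

    def __init__(self, model: CooccurrenceModel):
        super().__init__()
        self.model = model

    def _score(self, w1: str, w2: str) -> float:
        return vector_similarity(w1, w2, self.model)
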