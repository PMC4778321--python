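"""Thresholded, idf-weighted text-to-text semantic similarity.

The metric is a modified Mihalcea-style combination of word-to-word
similarity and word specificity::

    sim(T1, T2) = 1/2 * [  sum_{w in S(T1,T2,theta)} maxSim(w, T2) * idf(w)
                          ----------------------------------------------
                                  sum_{w in {T1}} idf(w)
                        + (the symmetric T2 -> T1 term) ]

where ``maxSim(w, T)`` is the highest word similarity between ``w`` and any
token of ``T``, ``idf(w)`` is the plain (un-logged) ratio of corpus size to
document frequency, and ``S(T1, T2, theta)`` keeps only words whose best
match reaches the threshold ``theta``.  The threshold removes irrelevant
words whose low-but-positive similarity would otherwise leak into the score
(the "male/female pelvic inflammatory disease" effect); ``theta = 0``
recovers the unthresholded metric exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

from .tokenizers import TokenizedText, WhitespaceTokenizer
from .word_similarity import WordSimilarityBackend

__all__ = [
    "IdfModel",
    "SimilarityConfig",
    "idf",
    "max_sim",
    "text_similarity",
]


class SupportsIdf(Protocol):
    def idf(self, w: str) -> float: ...


@dataclass
class IdfModel:
    """Document frequencies: ``idf(w) = n_docs / df(w)`` (no logarithm).

    Unseen words get ``df = 1`` (maximally specific); a ``log_variant``
    switch computes ``1 + log(n_docs / df)`` instead, for experimentation.
    """

    n_docs: int
    df: dict[str, int] = field(default_factory=dict)
    log_variant: bool = False

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("IdfModel requires n_docs >= 1")
        for w, d in self.df.items():
            if not 1 <= d <= self.n_docs:
                raise ValueError(f"df({w!r}) = {d} outside [1, n_docs={self.n_docs}]")

    def idf(self, w: str) -> float:
        ratio = self.n_docs / self.df.get(w, 1)
        return 1.0 + math.log(ratio) if self.log_variant else ratio

    @classmethod
    def uniform(cls) -> "IdfModel":
        """Every word weighted 1: no corpus statistics available."""
        return cls(n_docs=1)

    @classmethod
    def from_corpus(cls, docs: Iterable[Sequence[str] | TokenizedText]) -> "IdfModel":
        df: dict[str, int] = {}
        n = 0
        for doc in docs:
            n += 1
            tokens = doc.tokens if isinstance(doc, TokenizedText) else doc
            for w in set(tokens):
                df[w] = df.get(w, 0) + 1
        if n == 0:
            raise ValueError("cannot build an IdfModel from an empty corpus")
        return cls(n, df)

    @classmethod
    def from_lines(
        cls, path: str | Path, tokenizer: Callable[[str], TokenizedText] | None = None
    ) -> "IdfModel":
        """One document per line; a tokenizer segments raw lines."""
        tok = tokenizer or WhitespaceTokenizer()
        lines = [
            l for l in Path(path).read_text(encoding="utf-8").splitlines() if l.strip()
        ]
        return cls.from_corpus([tok(l) for l in lines])

    @classmethod
    def from_dir(
        cls, path: str | Path, tokenizer: Callable[[str], TokenizedText] | None = None
    ) -> "IdfModel":
        """One document per file in a directory."""
        tok = tokenizer or WhitespaceTokenizer()
        docs = [
            tok(p.read_text(encoding="utf-8"))
            for p in sorted(Path(path).iterdir())
            if p.is_file()
        ]
        return cls.from_corpus(docs)

    def save(self, path: str | Path) -> None:
        lines = [f"#n_docs={self.n_docs}"]
        lines += [f"{w}\t{d}" for w, d in sorted(self.df.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "IdfModel":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or not lines[0].startswith("#n_docs="):
            raise ValueError(f"{path}: missing '#n_docs=' header")
        n = int(lines[0].split("=", 1)[1])
        df = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            w, d = line.split("\t")
            df[w] = int(d)
        return cls(n, df)


def idf(w: str, model: SupportsIdf) -> float:
    """Inverse document frequency of ``w`` under ``model``."""
    return model.idf(w)


@dataclass
class SimilarityConfig:
    """Everything the text metric needs: backend, idf weights, threshold.

    ``theta`` is the word-similarity threshold in [0, 1]; ``tokenizer`` turns
    raw strings into token sequences (whitespace split by default, suitable
    for pre-segmented input).
    """

    backend: WordSimilarityBackend
    idf: SupportsIdf
    theta: float = 0.0
    tokenizer: Callable[[str], TokenizedText] = field(default_factory=WhitespaceTokenizer)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def max_sim(w: str, T: TokenizedText, backend: WordSimilarityBackend) -> float:
    """Highest word similarity between ``w`` and any token of ``T``.

    An identical token short-circuits to 1.0 under every backend, including a
    vector backend with no distributional evidence for the word.
    """
    if not T.tokens:
        raise ValueError("max_sim requires a non-empty text")
    if w in T.tokens:
        return 1.0
    return max(backend.similarity(w, t) for t in T.tokens)


def _directional(T1: TokenizedText, T2: TokenizedText, config: SimilarityConfig) -> float:
    num = 0.0
    den = 0.0
    for w in T1.tokens:  # duplicate tokens each contribute an occurrence
        weight = config.idf.idf(w)
        den += weight
        ms = max_sim(w, T2, config.backend)
        if ms >= config.theta:
            num += ms * weight
    return num / den


def text_similarity(
    T1: TokenizedText, T2: TokenizedText, config: SimilarityConfig
) -> float:
    """The thresholded, idf-weighted semantic similarity of two texts.

    Symmetric; in [0, 1]; 0 (with a warning) if either text is empty after
    preprocessing, so degenerate inputs never abort batch encoding.
    """
    if not T1.tokens or not T2.tokens:
        warnings.warn("text_similarity over an empty text: returning 0", stacklevel=2)
        return 0.0
    return 0.5 * (_directional(T1, T2, config) + _directional(T2, T1, config))
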