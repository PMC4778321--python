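"""Tokenization and content filtering.

Chinese text carries no word delimiters, so the similarity metric consumes
pre-tokenized text.  The default tokenizer is a deterministic greedy
longest-match dictionary segmenter whose dictionary is the union of the
terminology terms' segments and any user lexicon; whitespace in the input is
treated as a hard segment boundary, so pre-segmented input passes through
unchanged.  Any callable ``str -> TokenizedText`` can be plugged in instead.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "TokenizedText",
    "GreedyTokenizer",
    "WhitespaceTokenizer",
    "is_content_token",
    "content_chars",
]


@dataclass(frozen=True)
class TokenizedText:
    """An ordered token sequence; the character sequence is their join."""

    tokens: tuple[str, ...]

    @property
    def chars(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


class WhitespaceTokenizer:
    """Split on whitespace: the pass-through for pre-segmented input."""

    def __call__(self, text: str) -> TokenizedText:
        return TokenizedText(tuple(text.split()))


class GreedyTokenizer:
    """Greedy longest-match dictionary segmentation.

    At each position the longest dictionary word is consumed; characters that
    start no dictionary word become single-character tokens.  Whitespace is a
    segment boundary and carries no characters.
    """

    def __init__(self, lexicon: Iterable[str]):
        self.lexicon = frozenset(w for w in lexicon if w)
        self._max_len = max((len(w) for w in self.lexicon), default=1)

    def __call__(self, text: str) -> TokenizedText:
        tokens: list[str] = []
        for chunk in text.split():
            i = 0
            while i < len(chunk):
                for j in range(min(len(chunk), i + self._max_len), i, -1):
                    if chunk[i:j] in self.lexicon:
                        tokens.append(chunk[i:j])
                        i = j
                        break
                else:
                    tokens.append(chunk[i])
                    i += 1
        return TokenizedText(tuple(tokens))


def _is_content_char(ch: str) -> bool:
    cat = unicodedata.category(ch)
    # numerals (N*), punctuation (P*), separators (Z*) and symbols (S*)
    # carry no lexical content for distributional statistics
    return cat[0] not in "NPZS" and not ch.isspace()


def content_chars(token: str) -> str:
    """The content characters of a token (numerals/punctuation stripped)."""
    return "".join(ch for ch in token if _is_content_char(ch))


def is_content_token(token: str, stopwords: frozenset[str] = frozenset()) -> bool:
    """A content token has at least one content character and is no stop word."""
    if token in stopwords:
        return False
    return bool(content_chars(token))
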