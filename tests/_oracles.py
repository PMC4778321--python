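"""Independent reference implementations used only as test oracles.

Deliberately written with different algorithms/styles than the package:
memoized recursion instead of tabulated DP, hand-rolled BFS instead of graph
libraries, quadratic loops instead of windowed streaming, straight-line
transcription of the similarity formula instead of the cached/structured
production path.
"""

from __future__ import annotations

import unicodedata
from collections import Counter, deque
from functools import lru_cache


# -- longest common subsequence (memoized recursion) ------------------------
def lcs_len_oracle(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def lcs_sim_oracle(a: str, b: str) -> float:
    l = lcs_len_oracle(a, b)
    return l / (len(a) + len(b) - l)


# -- shortest path by hand-rolled BFS ---------------------------------------
def bfs_distance(edges: list[tuple[str, str]], s1: str, s2: str) -> float:
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if s1 == s2:
        return 0.0
    seen = {s1}
    frontier = deque([(s1, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nxt in adj.get(node, ()):
            if nxt == s2:
                return float(d + 1)
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    return float("inf")


# -- naive quadratic co-occurrence counts -----------------------------------
def _content(tok: str) -> str:
    return "".join(
        ch
        for ch in tok
        if unicodedata.category(ch)[0] not in "NPZS" and not ch.isspace()
    )


def naive_cooccurrence(
    docs: list[list[str]], mode: str, window: int, stopwords: frozenset[str] = frozenset()
) -> Counter:
    """Counter of (word, context-unit) pairs, by exhaustive pairwise scan."""
    counts: Counter = Counter()
    for doc in docs:
        content = [t for t in doc if t not in stopwords and _content(t)]
        if mode == "word_dims":
            for i, w in enumerate(content):
                for j, u in enumerate(content):
                    if i != j and abs(i - j) <= window:
                        counts[(w, u)] += 1
        else:
            # character stream with each token's span; a char is context of a
            # token iff it lies within `window` positions outside the span
            stream: list[str] = []
            spans: list[tuple[int, int]] = []
            for t in content:
                cs = _content(t)
                spans.append((len(stream), len(stream) + len(cs)))
                stream.extend(cs)
            for w, (a, b) in zip(content, spans):
                for k, ch in enumerate(stream):
                    if (a - window <= k < a) or (b <= k < b + window):
                        counts[(w, ch)] += 1
    return counts


# -- straight-line transcription of the text-similarity formula -------------
def mihalcea_oracle(tokens1, tokens2, pair_sim, idf_of, theta=None) -> float:
    """The (optionally thresholded) idf-weighted metric, written linearly.

    ``theta=None`` gives the original unthresholded form; identical tokens
    score 1 under any pair measure.
    """

    def max_sim(w, T):
        return max(1.0 if w == t else pair_sim(w, t) for t in T)

    def one_way(A, B):
        num = 0.0
        den = 0.0
        for w in A:
            ms = max_sim(w, B)
            if theta is None or ms >= theta:
                num += ms * idf_of(w)
            den += idf_of(w)
        return num / den

    return 0.5 * (one_way(tokens1, tokens2) + one_way(tokens2, tokens1))


# -- brute-force flat argmax ------------------------------------------------
def brute_force_flat(D, system, config, text_similarity_fn):
    """Exhaustive argmax over searchable subcategories (plus undivided
    categories), ties to the smallest code string; independent of the
    encoder's iteration strategy."""
    candidates = system.searchable_subcategories() + system.undivided_categories()
    best_raw, best_sim = None, -1.0
    for raw in candidates:
        T = config.tokenizer(system.text(raw))
        sim = text_similarity_fn(D, T, config)
        if sim > best_sim or (sim == best_sim and raw < best_raw):
            best_raw, best_sim = raw, sim
    return best_raw, best_sim, len(candidates)
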