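"""Flat and hierarchical example-based code assignment.

The flat coder returns ``argmax_c sim(D, T_c)`` over every searchable
subcategory.  The hierarchical coder exploits the code tree: it first picks
the best section, then the best category under it, then the best
subcategory under that category — examining on the order of
(#sections + categories-in-one-section + subcategories-in-one-category)
candidates instead of every subcategory, and resisting coincidental
near-matches in unrelated chapters.  The similarity of the finally chosen
code is reported as the confidence of the assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .codes import Code, Level
from .codesystem import CodeSystem
from .text_similarity import SimilarityConfig, text_similarity
from .tokenizers import TokenizedText

__all__ = ["EncodingResult", "EncoderError", "encode_flat", "encode_hierarchical", "encode_batch"]


class EncoderError(ValueError):
    """Raised when a system has nothing searchable to encode against."""


@dataclass
class EncodingResult:
    """Outcome of encoding one diagnosis.

    ``code`` is absent on abstention (best similarity at some level at or
    below the floor); ``trace`` records the (level, code, similarity) descent
    chain; ``confidence`` equals the similarity at the final trace step.
    """

    code: Code | None
    confidence: float
    trace: list[tuple[str, Code, float]] = field(default_factory=list)
    n_candidates_evaluated: int = 0
    query: str = ""

    @property
    def abstained(self) -> bool:
        return self.code is None


def _as_text(D: TokenizedText | str, config: SimilarityConfig) -> TokenizedText:
    return D if isinstance(D, TokenizedText) else config.tokenizer(D)


def _description_tokens(system: CodeSystem, config: SimilarityConfig):
    """Tokenized T_c per code, memoized on the system per tokenizer."""
    key = id(config.tokenizer)
    cache = system._token_cache.get(key)
    if cache is None:
        cache = system._token_cache[key] = {}
    return cache


def _tokens_for(system: CodeSystem, raw: str, config: SimilarityConfig) -> TokenizedText:
    cache = _description_tokens(system, config)
    toks = cache.get(raw)
    if toks is None:
        toks = cache[raw] = config.tokenizer(system.text(raw))
    return toks


def _argmax(
    D: TokenizedText,
    candidates: Sequence[str],
    system: CodeSystem,
    config: SimilarityConfig,
) -> tuple[str, float, int]:
    """Best candidate by similarity; ties go to the lexicographically
    smallest code (candidates are iterated in sorted order, strict '>')."""
    best_raw, best_sim = "", -1.0
    n = 0
    for raw in sorted(candidates):
        sim = text_similarity(D, _tokens_for(system, raw, config), config)
        n += 1
        if sim > best_sim:
            best_raw, best_sim = raw, sim
    return best_raw, best_sim, n


def _flat_candidates(system: CodeSystem) -> list[str]:
    # searchable subcategories, plus undivided categories (terms filed at the
    # category with no searchable subcategory below): those surface at
    # category level rather than failing silently
    return system.searchable_subcategories() + system.undivided_categories()


def encode_flat(
    D: TokenizedText | str,
    system: CodeSystem,
    config: SimilarityConfig,
    abstain_floor: float = 0.0,
) -> EncodingResult:
    """``argmax_c sim(D, T_c)`` over all searchable subcategory codes."""
    D_text = _as_text(D, config)
    candidates = _flat_candidates(system)
    if not candidates:
        raise EncoderError("code system has no searchable subcategory")
    best_raw, best_sim, n = _argmax(D_text, candidates, system, config)
    best = system.nodes[best_raw].code
    if best_sim <= abstain_floor:
        return EncodingResult(None, best_sim, [(best.level.value, best, best_sim)], n,
                              query=D_text.chars)
    return EncodingResult(best, best_sim, [(best.level.value, best, best_sim)], n,
                          query=D_text.chars)


def encode_hierarchical(
    D: TokenizedText | str,
    system: CodeSystem,
    config: SimilarityConfig,
    abstain_floor: float = 0.0,
) -> EncodingResult:
    """Descend section -> category -> subcategory, taking the most similar
    searchable code at each level."""
    D_text = _as_text(D, config)
    sections = [s.raw for s in system.sections if system.searchable(s.raw)]
    if not sections:
        raise EncoderError("code system has no searchable section")
    trace: list[tuple[str, Code, float]] = []
    n_total = 0

    def descend(candidates: Iterable[str]) -> tuple[Code, float] | None:
        nonlocal n_total
        cand = [c for c in candidates if system.searchable(c)]
        if not cand:
            return None
        raw, sim, n = _argmax(D_text, cand, system, config)
        n_total += n
        code = system.nodes[raw].code
        trace.append((code.level.value, code, sim))
        return code, sim

    sec = descend(sections)
    if sec is None or sec[1] <= abstain_floor:
        conf = sec[1] if sec else 0.0
        return EncodingResult(None, conf, trace, n_total, query=D_text.chars)
    cat = descend(system.children(sec[0].raw))
    if cat is None or cat[1] <= abstain_floor:
        conf = cat[1] if cat else sec[1]
        return EncodingResult(None, conf, trace, n_total, query=D_text.chars)
    sub = descend(system.children(cat[0].raw))
    if sub is None:
        # undivided category: the category code itself is the final answer
        return EncodingResult(cat[0], cat[1], trace, n_total, query=D_text.chars)
    if sub[1] <= abstain_floor:
        return EncodingResult(None, sub[1], trace, n_total, query=D_text.chars)
    return EncodingResult(sub[0], sub[1], trace, n_total, query=D_text.chars)


def encode_batch(
    queries: Iterable[TokenizedText | str],
    system: CodeSystem,
    config: SimilarityConfig,
    method: str = "hierarchical",
    abstain_floor: float = 0.0,
) -> list[EncodingResult]:
    """Encode many diagnoses with one method ("flat" or "hierarchical")."""
    if method not in ("flat", "hierarchical", "hier"):
        raise ValueError(f"unknown method {method!r}")
    fn = encode_flat if method == "flat" else encode_hierarchical
    return [fn(q, system, config, abstain_floor) for q in queries]
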