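"""Seeded generators for every external resource the coder consumes.

The real inputs — a national standard diagnostic terminology, a hospital
discharge-summary corpus, a lexical knowledge base — are not redistributable,
so this module generates structurally faithful stand-ins: a section/category/
subcategory code skeleton with multi-instance terminology entries built from
a synthetic CJK-range vocabulary, query sets perturbed by synonym swaps and
character edits, a topic-structured corpus in which same-category words
co-occur preferentially, and a small rooted sememe taxonomy with partial
lexicon coverage (the uncovered remainder exercises the string-similarity
fallback).  Everything is deterministic under a fixed seed.

Two hand-constructed fixtures reproduce specific failure mechanisms at exact
similarity values: :func:`near_miss_fixture` (an irrelevant low-similarity
word flips the argmax unless the word-similarity threshold removes it) and
:func:`hierarchical_rescue_fixture` (a coincidental strong match in the
wrong chapter fools the flat coder but not the hierarchical one).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .codes import Code, parse_code
from .codesystem import TerminologyEntry
from .evaluation import GoldInstance
from .word_similarity import SememeTaxonomy

__all__ = [
    "FixtureSpec",
    "TerminologyFixture",
    "gen_code_system",
    "gen_queries",
    "gen_corpus",
    "gen_sememe_taxonomy",
    "near_miss_fixture",
    "hierarchical_rescue_fixture",
    "write_fixture",
]

_CJK_BASE = 0x4E00
_CJK_SPAN = 4000


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and noise parameters of a synthetic coding study.

    Defaults mirror the real terminology's ratios at small scale: a few
    contiguous sections, a handful of categories each, up to a few
    subcategories per category, and about two instance terms per
    subcategory (the real library averages 2.28).
    """

    n_sections: int = 3
    n_categories_per_section: int = 4
    n_subcats_per_category: int = 3
    n_terms_per_subcat: int = 2
    vocab_size: int = 240
    term_length: tuple[int, int] = (2, 3)
    synonym_rate: float = 0.0
    char_edit_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_sections",
            "n_categories_per_section",
            "n_subcats_per_category",
            "n_terms_per_subcat",
            "vocab_size",
        ):
            if getattr(self, name) < 1:
                raise FixtureSpecError(f"{name} must be >= 1")
        if self.n_categories_per_section > 100:
            raise FixtureSpecError(
                "a letter offers only 100 category slots per section"
            )
        if self.n_subcats_per_category > 10:
            raise FixtureSpecError("at most 10 subcategories fit under a category")
        for rate in (self.synonym_rate, self.char_edit_rate):
            if not 0.0 <= rate <= 1.0:
                raise FixtureSpecError("noise rates must lie in [0, 1]")
        if not 1 <= self.term_length[0] <= self.term_length[1]:
            raise FixtureSpecError("term_length must be a non-empty increasing range")


@dataclass
class TerminologyFixture:
    """A generated code system plus the side tables the pipeline needs."""

    spec: FixtureSpec
    sections: list[Code]
    entries: list[TerminologyEntry]
    term_tokens: dict[str, tuple[str, ...]]  # term -> its word segmentation
    lexicon: set[str]  # every word incl. synonyms, for the tokenizer
    synonyms: dict[str, str]  # base word -> synonym (shares first char)
    category_words: dict[str, list[str]]  # category raw -> topic word pool
    background_words: list[str]


def _fresh_word(rng: random.Random, used: set[str], length: int = 2) -> str:
    while True:
        w = "".join(
            chr(_CJK_BASE + rng.randrange(_CJK_SPAN)) for _ in range(length)
        )
        if w not in used:
            used.add(w)
            return w


def gen_code_system(spec: FixtureSpec) -> TerminologyFixture:
    """Generate sections and terminology entries under ``spec``.

    Within a category every term starts with the category's head word, so
    descriptions agree more within a category than across categories and
    hierarchical descent is informative.  Every subcategory receives exactly
    ``n_terms_per_subcat`` terms.
    """
    rng = random.Random(spec.seed)
    used: set[str] = set()
    n_base_needed = (
        spec.n_sections * spec.n_categories_per_section * (1 + spec.n_subcats_per_category)
    )
    if spec.vocab_size < n_base_needed:
        raise FixtureSpecError(
            f"vocab_size {spec.vocab_size} cannot seed {n_base_needed} head/subcategory words"
        )

    sections: list[Code] = []
    entries: list[TerminologyEntry] = []
    term_tokens: dict[str, tuple[str, ...]] = {}
    category_words: dict[str, list[str]] = {}
    letter_idx, slot = 0, 0
    n_words = 0

    def draw(length: int = 2) -> str:
        nonlocal n_words
        n_words += 1
        return _fresh_word(rng, used, length)

    for _ in range(spec.n_sections):
        if slot + spec.n_categories_per_section > 100:
            letter_idx += 1
            slot = 0
        if letter_idx >= 26:
            raise FixtureSpecError("section skeleton exceeds the A-Z letter space")
        letter = chr(ord("A") + letter_idx)
        lo, hi = slot, slot + spec.n_categories_per_section - 1
        sections.append(parse_code(f"{letter}{lo:02d}-{letter}{hi:02d}"))
        for c in range(lo, hi + 1):
            cat = f"{letter}{c:02d}"
            head = draw()
            pool = [head]
            for s in range(spec.n_subcats_per_category):
                subword = draw()
                pool.append(subword)
                for k in range(spec.n_terms_per_subcat):
                    length = rng.randint(*spec.term_length)
                    n_extra = max(length - 2, 1 if k > 0 else 0)
                    extras = [draw() for _ in range(n_extra)]
                    tokens = tuple([head, subword] + extras)
                    term = "".join(tokens)
                    pool.extend(extras)
                    term_tokens[term] = tokens
                    entries.append(
                        TerminologyEntry(term, parse_code(f"{cat}.{s}{k:02d}"))
                    )
            category_words[cat] = pool
        slot += spec.n_categories_per_section

    synonyms: dict[str, str] = {}
    for cat, pool in category_words.items():
        syns = []
        for w in list(pool):
            synonyms[w] = w[0] + _fresh_word(rng, used, 1)
            syns.append(synonyms[w])
        pool.extend(syns)
    background = [_fresh_word(rng, used) for _ in range(10)]
    lexicon = set(synonyms) | set(synonyms.values()) | set(background)
    return TerminologyFixture(
        spec=spec,
        sections=sections,
        entries=entries,
        term_tokens=term_tokens,
        lexicon=lexicon,
        synonyms=synonyms,
        category_words=category_words,
        background_words=background,
    )


def gen_queries(
    fixture: TerminologyFixture,
    synonym_rate: float | None = None,
    char_edit_rate: float | None = None,
    seed: int | None = None,
    n_queries: int | None = None,
) -> list[GoldInstance]:
    """Perturbed copies of terminology terms with their gold subcategories.

    Each query starts from a terminology term; with probability
    ``synonym_rate`` one token is replaced by its synonym-table entry, and
    with probability ``char_edit_rate`` one character is substituted.  Zero
    noise yields verbatim terms.
    """
    spec = fixture.spec
    synonym_rate = spec.synonym_rate if synonym_rate is None else synonym_rate
    char_edit_rate = spec.char_edit_rate if char_edit_rate is None else char_edit_rate
    rng = random.Random(spec.seed + 7919 if seed is None else seed)
    pool = fixture.entries
    chosen = (
        pool if n_queries is None else [pool[rng.randrange(len(pool))] for _ in range(n_queries)]
    )
    out: list[GoldInstance] = []
    for entry in chosen:
        tokens = list(fixture.term_tokens[entry.term])
        if rng.random() < synonym_rate:
            idx = [i for i, t in enumerate(tokens) if t in fixture.synonyms]
            if idx:
                i = rng.choice(idx)
                tokens[i] = fixture.synonyms[tokens[i]]
        if rng.random() < char_edit_rate:
            i = rng.randrange(len(tokens))
            chars = list(tokens[i])
            j = rng.randrange(len(chars))
            old = chars[j]
            while chars[j] == old:
                chars[j] = chr(_CJK_BASE + rng.randrange(_CJK_SPAN))
            tokens[i] = "".join(chars)
        out.append(GoldInstance("".join(tokens), entry.filing_code.subcategory
                                if entry.filing_code.level.value == "subcategory"
                                else entry.filing_code))
    return out


def gen_corpus(
    fixture: TerminologyFixture,
    n_docs: int = 80,
    doc_length: int = 30,
    seed: int = 0,
    topic_weight: float = 0.8,
) -> list[list[str]]:
    """A topic-structured token corpus: each document is dominated by one
    category's word pool (synonyms included), diluted with shared background
    words, so same-category words co-occur preferentially."""
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    rng = random.Random(seed)
    cats = sorted(fixture.category_words)
    docs: list[list[str]] = []
    for d in range(n_docs):
        cat = cats[d % len(cats)]
        pool = fixture.category_words[cat]
        doc = [
            rng.choice(pool) if rng.random() < topic_weight else rng.choice(fixture.background_words)
            for _ in range(doc_length)
        ]
        docs.append(doc)
    return docs


def gen_sememe_taxonomy(
    fixture: TerminologyFixture,
    depth: int = 3,
    seed: int = 0,
    coverage: float = 0.9,
) -> SememeTaxonomy:
    """A rooted sememe tree mirroring the category structure.

    Each category owns a sememe; each base word a leaf under its category's
    sememe, so same-category words sit two edges apart and cross-category
    words four.  A synonym shares its base word's leaf (similarity 1 under
    the knowledge backend).  Only a ``coverage`` fraction of base words
    enters the lexicon; the rest fall back to string similarity.
    """
    if depth < 2:
        raise ValueError("taxonomy depth must be >= 2")
    rng = random.Random(seed)
    edges: list[tuple[str, str]] = []
    root = "sem:root"
    anchor = root
    for level in range(depth - 2):  # optional chain toward the root
        nxt = f"sem:mid{level}"
        edges.append((nxt, anchor))
        anchor = nxt
    lexicon: dict[str, tuple[tuple[str, ...], ...]] = {}
    for cat in sorted(fixture.category_words):
        cat_sem = f"sem:{cat}"
        edges.append((cat_sem, anchor))
        for k, w in enumerate(fixture.category_words[cat]):
            if w in fixture.synonyms.values():
                continue  # synonyms attach to their base word's leaf below
            leaf = f"sem:{cat}:{k}"
            edges.append((leaf, cat_sem))
            if rng.random() < coverage:
                lexicon[w] = ((leaf,),)
                syn = fixture.synonyms.get(w)
                if syn:
                    lexicon[syn] = ((leaf,),)
    bg_sem = "sem:background"
    edges.append((bg_sem, anchor))
    for k, w in enumerate(fixture.background_words):
        leaf = f"sem:background:{k}"
        edges.append((leaf, bg_sem))
        if rng.random() < coverage:
            lexicon[w] = ((leaf,),)
    return SememeTaxonomy.from_edges(edges, lexicon)


# ---------------------------------------------------------------------------
# hand-constructed mechanism fixtures
# ---------------------------------------------------------------------------
def _chars(n: int, start: int = 0) -> list[str]:
    return [chr(_CJK_BASE + start + i) for i in range(n)]


def near_miss_fixture():
    """A query whose irrelevant first word drags the argmax to a distractor.

    The query is [m, p].  The gold code's term is [f, p]: p matches exactly,
    m matches f only weakly (LCS 1/3).  The distractor's term is [x, y] with
    moderate matches lcs(m, x) = 2/3 and lcs(p, y) = 3/4 — together they
    outweigh the gold code when every low similarity counts (theta = 0), but
    at theta = 0.7 only exact-and-strong matches survive and the gold code
    wins.  Several verbatim queries pad the gold set.

    Returns (sections, entries, gold, lexicon, tricky_query, gold_code,
    distractor_code).
    """
    c = _chars(24, start=600)
    m = c[0] + c[1]
    f = c[0] + c[2]
    p = c[3] + c[4] + c[5]
    x = c[0] + c[1] + c[6]
    y = c[3] + c[4] + c[5] + c[7]
    clean = [c[8] + c[9] + c[10] + c[11], c[12] + c[13] + c[14] + c[15],
             c[16] + c[17] + c[18] + c[19], c[20] + c[21] + c[22] + c[23]]
    clean_tokens = [(t[:2], t[2:]) for t in clean]
    sections = [parse_code("A00-A09"), parse_code("B00-B09")]
    entries = [
        TerminologyEntry(clean[0], parse_code("A00.000")),
        TerminologyEntry(f + p, parse_code("A01.000")),
        TerminologyEntry(clean[1], parse_code("A02.000")),
        TerminologyEntry(x + y, parse_code("B02.000")),
        TerminologyEntry(clean[2], parse_code("B03.000")),
        TerminologyEntry(clean[3], parse_code("B04.000")),
    ]
    lexicon = {m, f, p, x, y} | {w for pair in clean_tokens for w in pair}
    gold = [
        GoldInstance(m + p, parse_code("A01.0")),
        GoldInstance(clean[0], parse_code("A00.0")),
        GoldInstance(clean[1], parse_code("A02.0")),
        GoldInstance(clean[2], parse_code("B03.0")),
        GoldInstance(clean[3], parse_code("B04.0")),
    ]
    return sections, entries, gold, lexicon, m + p, "A01.0", "B02.0"


def hierarchical_rescue_fixture():
    """The auricular-neuralgia construction: flat picks the wrong chapter.

    The query 耳神经痛 (ear neuralgia) belongs under H92.0, whose only term
    is 耳痛 (earache); but a nerve-chapter code G58.0 carries 肋间神经痛
    (intercostal neuralgia), whose exact 神经痛 match scores higher, so the
    flat argmax lands on G58.0.  The hierarchical coder compares whole
    sections first: the ear section's concatenated terms resemble the query
    more than the nerve section's, so the descent stays in H90-H95 and
    reaches H92.0.

    Returns (sections, entries, lexicon, query, correct_code, distractor_code).
    """
    sections = [parse_code("G40-G59"), parse_code("H90-H95")]
    entries = [
        TerminologyEntry("癫痫", parse_code("G40.000")),
        TerminologyEntry("偏头痛", parse_code("G43.000")),
        TerminologyEntry("面瘫", parse_code("G51.000")),
        TerminologyEntry("肋间神经痛", parse_code("G58.000")),
        TerminologyEntry("耳聋", parse_code("H90.000")),
        TerminologyEntry("耳鸣", parse_code("H91.000")),
        TerminologyEntry("耳痛", parse_code("H92.000")),
        TerminologyEntry("中耳炎", parse_code("H93.000")),
    ]
    lexicon = {"耳", "耳痛", "耳聋", "耳鸣", "中耳炎", "肋间", "神经痛",
               "癫痫", "偏头痛", "面瘫"}
    return sections, entries, lexicon, "耳神经痛", "H92.0", "G58.0"


def write_fixture(
    fixture: TerminologyFixture,
    outdir: str | Path,
    n_docs: int = 80,
    doc_length: int = 30,
    taxonomy_coverage: float = 0.9,
) -> dict[str, Path]:
    """Write every generated artifact in its on-disk exchange format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "terminology": outdir / "terminology.tsv",
        "sections": outdir / "sections.txt",
        "lexicon": outdir / "lexicon.txt",
        "gold": outdir / "gold.tsv",
        "corpus": outdir / "corpus.txt",
        "taxonomy_edges": outdir / "taxonomy.edges.tsv",
        "taxonomy_lexicon": outdir / "taxonomy.lexicon.tsv",
    }
    paths["terminology"].write_text(
        "\n".join(f"{e.term}\t{e.code.raw}" for e in fixture.entries) + "\n",
        encoding="utf-8",
    )
    paths["sections"].write_text(
        "\n".join(s.raw for s in fixture.sections) + "\n", encoding="utf-8"
    )
    paths["lexicon"].write_text(
        "\n".join(sorted(fixture.lexicon)) + "\n", encoding="utf-8"
    )
    gold = gen_queries(fixture)
    paths["gold"].write_text(
        "\n".join(f"{g.diagnosis}\t{g.code.raw}" for g in gold) + "\n",
        encoding="utf-8",
    )
    corpus = gen_corpus(fixture, n_docs=n_docs, doc_length=doc_length, seed=fixture.spec.seed)
    paths["corpus"].write_text(
        "\n".join(" ".join(doc) for doc in corpus) + "\n", encoding="utf-8"
    )
    tax = gen_sememe_taxonomy(fixture, seed=fixture.spec.seed, coverage=taxonomy_coverage)
    tax.save(paths["taxonomy_edges"], paths["taxonomy_lexicon"])
    return paths
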