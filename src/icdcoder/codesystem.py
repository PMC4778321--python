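"""Code-system construction: terminology entries, the hierarchy, and T_c texts.

The example-based coder treats each code ``c`` as described by a text ``T_c``
obtained by concatenating every standard diagnosis term filed under ``c`` or
its descendants (e.g. ``T_{A01.0}`` is the join of the three typhoid terms
filed at A01.000/001/002).  Codes with no terminology anywhere below them get
an empty description and are flagged non-searchable: they can never be
compared against a diagnosis, let alone returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .codes import Code, Level, parse_code, section_contains

__all__ = [
    "TerminologyEntry",
    "CodeSystem",
    "CodeSystemBuildError",
    "build_code_system",
    "read_terminology",
    "read_sections",
]


class CodeSystemBuildError(ValueError):
    """Raised for orphan categories or malformed section lists."""


@dataclass(frozen=True)
class TerminologyEntry:
    """One standard-diagnosis row: a term and its instance-level code.

    Instance-level codes are filed at their subcategory truncation;
    subcategory- and category-level codes are filed at themselves
    (tolerant ingestion of mixed-precision sources).
    """

    term: str
    code: Code

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError("terminology term is empty after whitespace stripping")
        if self.code.level not in (Level.INSTANCE, Level.SUBCATEGORY, Level.CATEGORY):
            raise ValueError(
                f"terminology entry code {self.code.raw!r} must be instance, "
                "subcategory or category level"
            )

    @property
    def filing_code(self) -> Code:
        """The hierarchy node this entry's term is filed under."""
        if self.code.level is Level.INSTANCE:
            return self.code.subcategory
        return self.code


@dataclass
class _Node:
    code: Code
    parent: str | None
    children: list[str] = field(default_factory=list)
    terms: list[str] = field(default_factory=list)  # directly filed terms, in order
    text: str = ""  # T_c
    searchable: bool = False


class CodeSystem:
    """The section > category > subcategory tree with per-code texts T_c."""

    def __init__(self, sections: list[Code], entries: list[TerminologyEntry]):
        self.sections = sections
        self.entries = entries
        self.nodes: dict[str, _Node] = {}
        self._token_cache: dict[int, dict] = {}
        self._build()

    # -- construction -----------------------------------------------------
    def _build(self) -> None:
        seen_ranges: list[Code] = []
        for sec in self.sections:
            if sec.level is not Level.SECTION:
                raise CodeSystemBuildError(f"{sec.raw!r} in section list is not a section")
            self.nodes[sec.raw] = _Node(sec, parent=None)
            seen_ranges.append(sec)

        orphans: list[str] = []
        for entry in self.entries:
            filing = entry.filing_code
            cat = filing.category
            covering = [s for s in seen_ranges if section_contains(s, cat)]
            if not covering:
                orphans.append(cat.raw)
                continue
            if len(covering) > 1:
                raise CodeSystemBuildError(
                    f"category {cat.raw} covered by overlapping sections "
                    f"{[s.raw for s in covering]}"
                )
            sec = covering[0]
            if cat.raw not in self.nodes:
                self.nodes[cat.raw] = _Node(cat, parent=sec.raw)
                self.nodes[sec.raw].children.append(cat.raw)
            if filing.level is Level.SUBCATEGORY:
                if filing.raw not in self.nodes:
                    self.nodes[filing.raw] = _Node(filing, parent=cat.raw)
                    self.nodes[cat.raw].children.append(filing.raw)
                self.nodes[filing.raw].terms.append(entry.term)
            else:  # category-level entry (undivided category)
                self.nodes[cat.raw].terms.append(entry.term)
        if orphans:
            raise CodeSystemBuildError(
                "categories not covered by any section: " + ", ".join(sorted(set(orphans)))
            )
        for node in self.nodes.values():
            node.children.sort()
        # T_c bottom-up: a node's text joins its own terms then its children's
        # texts in code order; duplicates kept, single-space joined.
        for sec in self.sections:
            self._concat(sec.raw)

    def _concat(self, raw: str) -> str:
        node = self.nodes[raw]
        pieces = list(node.terms)
        for child in node.children:
            child_text = self._concat(child)
            if child_text:
                pieces.append(child_text)
        node.text = " ".join(pieces)
        node.searchable = bool(node.text)
        return node.text

    # -- queries ----------------------------------------------------------
    def text(self, code: Code | str) -> str:
        raw = code.raw if isinstance(code, Code) else code
        return self.nodes[raw].text

    def searchable(self, code: Code | str) -> bool:
        raw = code.raw if isinstance(code, Code) else code
        return self.nodes[raw].searchable

    def children(self, code: Code | str) -> list[str]:
        raw = code.raw if isinstance(code, Code) else code
        return self.nodes[raw].children

    def iter_level(self, level: Level, searchable_only: bool = False) -> Iterable[_Node]:
        for node in self.nodes.values():
            if node.code.level is level and (node.searchable or not searchable_only):
                yield node

    def searchable_subcategories(self) -> list[str]:
        return sorted(n.code.raw for n in self.iter_level(Level.SUBCATEGORY, True))

    def undivided_categories(self) -> list[str]:
        """Searchable categories with no searchable subcategory below them."""
        out = []
        for node in self.iter_level(Level.CATEGORY, True):
            if not any(self.nodes[c].searchable for c in node.children):
                out.append(node.code.raw)
        return sorted(out)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "sections": [s.raw for s in self.sections],
            "entries": [[e.term, e.code.raw] for e in self.entries],
        }
        return json.dumps(doc, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CodeSystem":
        doc = json.loads(text)
        sections = [parse_code(s) for s in doc["sections"]]
        entries = [TerminologyEntry(t, parse_code(c)) for t, c in doc["entries"]]
        return cls(sections, entries)


def build_code_system(
    entries: list[TerminologyEntry], sections: list[Code]
) -> CodeSystem:
    """Build the hierarchy and populate every T_c bottom-up."""
    return CodeSystem(sections, entries)


def read_terminology(path: str | Path) -> list[TerminologyEntry]:
    """Read a UTF-8 TSV of ``term<TAB>code`` rows; ``#`` starts a comment line."""
    entries = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'term<TAB>code', got {line!r}")
        entries.append(TerminologyEntry(parts[0].strip(), parse_code(parts[1])))
    return entries


def read_sections(path: str | Path) -> list[Code]:
    """Read a section list, one ``Cxx-Cyy`` range per line."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code = parse_code(line)
        if code.level is not Level.SECTION:
            raise ValueError(f"{line!r} in section list is not a section range")
        out.append(code)
    return out
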