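"""ICD-10 code grammar, levels and hierarchy arithmetic.

ICD-10 organises diagnosis codes as section (a range such as ``A00-A09``),
category (``A01``), subcategory (``A01.0``) and, in instance terminologies
such as the Chinese standard diagnostic library, 6-digit instance codes
(``A01.000``).  Coding is conventionally reported at the subcategory
(4-digit) level; sections are never reference codes themselves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import total_ordering

__all__ = [
    "Level",
    "Code",
    "CodeParseError",
    "parse_code",
    "section_contains",
]


class Level(str, Enum):
    SECTION = "section"
    CATEGORY = "category"
    SUBCATEGORY = "subcategory"
    INSTANCE = "instance"


class CodeParseError(ValueError):
    """Raised when a raw string matches none of the four code grammars."""


_CATEGORY_RE = re.compile(r"^([A-Z])([0-9]{2})$")
_SUBCAT_RE = re.compile(r"^([A-Z])([0-9]{2})\.([0-9])([0-9])?$")
_INSTANCE_RE = re.compile(r"^([A-Z])([0-9]{2})\.([0-9])([0-9]{2})$")
_SECTION_RE = re.compile(r"^([A-Z][0-9]{2})-([A-Z][0-9]{2})$")


def _cat_key(cat: str) -> tuple[str, int]:
    return (cat[0], int(cat[1:3]))


@total_ordering
@dataclass(frozen=True)
class Code:
    """A parsed code at one of the four hierarchy levels."""

    raw: str
    level: Level

    def __str__(self) -> str:  # format() round-trips the raw string
        return self.raw

    def __lt__(self, other: "Code") -> bool:
        return self.raw < other.raw

    # -- truncations ------------------------------------------------------
    @property
    def category(self) -> "Code":
        """The 3-character category truncation (identity for categories)."""
        if self.level is Level.SECTION:
            raise ValueError(f"section code {self.raw!r} has no category truncation")
        return Code(self.raw[:3], Level.CATEGORY)

    @property
    def subcategory(self) -> "Code":
        """The 4-digit truncation: instances drop their trailing two digits."""
        if self.level is Level.INSTANCE:
            return Code(self.raw[:5], Level.SUBCATEGORY)
        if self.level is Level.SUBCATEGORY:
            # 5-character codes (e.g. Z99.99) truncate to the 4-digit form
            return self if len(self.raw) == 5 else Code(self.raw[:5], Level.SUBCATEGORY)
        raise ValueError(f"{self.raw!r} ({self.level.value}) has no subcategory truncation")

    @property
    def section_bounds(self) -> tuple[tuple[str, int], tuple[str, int]]:
        if self.level is not Level.SECTION:
            raise ValueError(f"{self.raw!r} is not a section code")
        lo, hi = self.raw.split("-")
        return _cat_key(lo), _cat_key(hi)


def parse_code(raw: str) -> Code:
    """Parse a raw string into a :class:`Code`, assigning its level by grammar.

    >>> parse_code("A01.000").level.value
    'instance'
    >>> parse_code("A01.000").subcategory.raw
    'A01.0'
    """
    raw = raw.strip()
    if _INSTANCE_RE.match(raw):
        return Code(raw, Level.INSTANCE)
    if _SUBCAT_RE.match(raw):
        return Code(raw, Level.SUBCATEGORY)
    if _CATEGORY_RE.match(raw):
        return Code(raw, Level.CATEGORY)
    m = _SECTION_RE.match(raw)
    if m:
        lo, hi = _cat_key(m.group(1)), _cat_key(m.group(2))
        if lo > hi:
            raise CodeParseError(
                f"section range {raw!r}: lower bound {m.group(1)} sorts above {m.group(2)}"
            )
        return Code(raw, Level.SECTION)
    raise CodeParseError(f"malformed code {raw!r}: matches no code grammar")


def section_contains(section: Code, category: Code) -> bool:
    """True iff ``category`` sorts within the section's inclusive range.

    Order is (letter, number); e.g. ``K29`` lies in ``K20-K31``.
    """
    if section.level is not Level.SECTION:
        raise ValueError(f"expected a section code, got {section.raw!r}")
    if category.level is not Level.CATEGORY:
        raise ValueError(f"expected a category code, got {category.raw!r}")
    lo, hi = section.section_bounds
    return lo <= _cat_key(category.raw) <= hi
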