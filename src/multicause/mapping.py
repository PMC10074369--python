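"""ICD-10 codes and the mapping of codes onto analysis categories.

Cause-of-death analysis rarely works at the level of individual ICD-10
codes: codes are grouped into a condensed list of mutually exclusive,
exhaustive categories, and all counting happens at category level.  This
module provides code normalisation, a pattern-based :class:`CategoryMapping`
(exact codes, code ranges, chapter-letter prefixes), and a shipped default
40-category list suitable for mortality at older ages.
"""

from __future__ import annotations

import csv
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "InvalidCodeError",
    "MappingError",
    "UnmappedCodeError",
    "UNCLASSIFIED",
    "normalize_code",
    "CategoryMapping",
    "default_mapping",
]

#: Category label assigned to unmappable codes in lenient mode.  It is never
#: a valid underlying-cause category.
UNCLASSIFIED = "Unclassified"

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[A-Z0-9]{1,2})?$")


class InvalidCodeError(ValueError):
    """Raised when a string is not a syntactically valid ICD-10 code."""


class MappingError(ValueError):
    """Raised when a category mapping is malformed (overlaps, bad patterns)."""


class UnmappedCodeError(KeyError):
    """Raised when no pattern in the mapping matches a code."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


def normalize_code(code: str) -> str:
    """Normalise an ICD-10 code: strip whitespace, upper-case, validate.

    Accepted shapes are a letter plus two digits, optionally followed by a
    dot and one or two further characters (e.g. ``"I25"``, ``"i25.1"``,
    ``"Y87.0"``).
    """
    cleaned = re.sub(r"\s+", "", str(code)).upper()
    if not _CODE_RE.match(cleaned):
        raise InvalidCodeError(f"not a valid ICD-10 code: {code!r}")
    return cleaned


# ---------------------------------------------------------------------------
# Interval arithmetic on the code space.
#
# Every code or pattern is represented as an integer interval on a grid with
# 100 positions per three-character "root" (letter + two digits): the root
# A00 occupies [0, 99], A01 [100, 199], ... Z99 the final block.  A fourth
# character (first decimal digit) selects a 10-wide sub-interval, a fifth a
# single point.  Containment of intervals is then exactly "this code falls
# under that pattern", and overlap checking is interval intersection.
# ---------------------------------------------------------------------------

_SPAN = 100  # grid positions per three-character root


def _root_index(letter: str, digits: str) -> int:
    return (ord(letter) - ord("A")) * 100 + int(digits)


def _code_interval(code: str) -> tuple[int, int]:
    """Closed integer interval covered by a normalised code."""
    base = _root_index(code[0], code[1:3]) * _SPAN
    if len(code) == 3:
        return base, base + _SPAN - 1
    sub = code[4:]
    if not sub.isdigit():
        # Alphanumeric subdivisions carry no ordinal meaning; treat the code
        # as its three-character root for mapping purposes.
        return base, base + _SPAN - 1
    if len(sub) == 1:
        lo = base + int(sub) * 10
        return lo, lo + 9
    lo = base + int(sub[0]) * 10 + int(sub[1])
    return lo, lo


def _pattern_interval(pattern: str) -> tuple[int, int]:
    """Closed integer interval covered by a mapping pattern.

    Patterns are a single chapter letter (``"V"``), an exact code
    (``"G30"``, ``"Y87.0"``) or a hyphenated range whose endpoints are codes
    (``"C18-C21"``, ``"Y87.1-Y87.9"``).
    """
    p = re.sub(r"\s+", "", pattern).upper()
    if re.fullmatch(r"[A-Z]", p):
        lo, _ = _code_interval(p + "00")
        _, hi = _code_interval(p + "99")
        return lo, hi
    if "-" in p:
        start_s, _, end_s = p.partition("-")
        lo, _ = _code_interval(normalize_code(start_s))
        _, hi = _code_interval(normalize_code(end_s))
        if hi < lo:
            raise MappingError(f"descending code range: {pattern!r}")
        return lo, hi
    return _code_interval(normalize_code(p))


@dataclass(frozen=True)
class _Entry:
    pattern: str
    lo: int
    hi: int
    category: str


@dataclass
class CategoryMapping:
    """An ordered, overlap-free mapping of ICD-10 code patterns to categories.

    Parameters
    ----------
    entries
        ``(pattern, category)`` pairs.  Patterns may be exact codes, code
        ranges (``"C18-C21"``), decimal ranges (``"Y87.1-Y87.9"``) or single
        chapter letters (``"V"``).
    categories
        Category labels in report order.  Defaults to order of first
        appearance among the entries.

    The categories are required to be mutually exclusive: any two patterns
    whose code sets intersect raise :class:`MappingError` at construction.
    """

    entries: list[tuple[str, str]]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        parsed: list[_Entry] = []
        seen_cats: list[str] = []
        for pattern, category in self.entries:
            try:
                lo, hi = _pattern_interval(pattern)
            except InvalidCodeError as exc:
                raise MappingError(f"bad pattern {pattern!r}: {exc}") from exc
            parsed.append(_Entry(pattern, lo, hi, category))
            if category not in seen_cats:
                seen_cats.append(category)
        if not self.categories:
            self.categories = seen_cats
        else:
            missing = set(seen_cats) - set(self.categories)
            if missing:
                raise MappingError(
                    f"entries reference categories not in the category list: {sorted(missing)}"
                )
        parsed.sort(key=lambda e: e.lo)
        for a, b in zip(parsed, parsed[1:]):
            if b.lo <= a.hi:
                raise MappingError(
                    f"overlapping patterns {a.pattern!r} ({a.category}) and "
                    f"{b.pattern!r} ({b.category}); categories must be mutually exclusive"
                )
        self._sorted = parsed
        self._starts = [e.lo for e in parsed]
        self._cache: dict[str, str] = {}

    # -- lookup -------------------------------------------------------------

    def _match_interval(self, lo: int, hi: int) -> str | None:
        i = bisect_right(self._starts, lo) - 1
        if i >= 0:
            e = self._sorted[i]
            if e.lo <= lo and hi <= e.hi:
                return e.category
        return None

    def map_code(self, code: str, lenient: bool = False) -> str:
        """Return the category for *code*.

        Matching tries the full code first, then its three-character root.
        Unmatched codes raise :class:`UnmappedCodeError`, or map to
        :data:`UNCLASSIFIED` when ``lenient`` is true.
        """
        norm = normalize_code(code)
        hit = self._cache.get(norm)
        if hit is not None:
            return hit
        cat = self._match_interval(*_code_interval(norm))
        if cat is None and len(norm) > 3:
            cat = self._match_interval(*_code_interval(norm[:3]))
        if cat is None:
            # not cached: the answer depends on the lenient flag
            if not lenient:
                raise UnmappedCodeError(f"no pattern matches code {norm!r}")
            return UNCLASSIFIED
        self._cache[norm] = cat
        return cat

    # -- introspection ------------------------------------------------------

    def chapter_letters(self) -> set[str]:
        """Chapter letters (first characters) covered by at least one pattern."""
        letters = set()
        for e in self._sorted:
            first = e.lo // (100 * _SPAN)
            last = e.hi // (100 * _SPAN)
            letters.update(chr(ord("A") + i) for i in range(first, last + 1))
        return letters

    def __len__(self) -> int:
        return len(self.categories)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "CategoryMapping":
        """Read a mapping from a CSV file with columns ``pattern,category``.

        Lines starting with ``#`` are comments.  Category order follows
        first appearance.
        """
        entries: list[tuple[str, str]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            rows = csv.reader(line for line in fh if not line.lstrip().startswith("#"))
            header = next(rows, None)
            if header is None or [h.strip().lower() for h in header[:2]] != ["pattern", "category"]:
                raise MappingError(f"{path}: expected header 'pattern,category'")
            for row in rows:
                if not row or not row[0].strip():
                    continue
                if len(row) < 2:
                    raise MappingError(f"{path}: row {row!r} lacks a category")
                entries.append((row[0].strip(), row[1].strip()))
        if not entries:
            raise MappingError(f"{path}: no mapping entries")
        return cls(entries)


def default_mapping() -> CategoryMapping:
    """The shipped 40-category mapping for deaths at older ages.

    Groups ICD-10 codes into 40 mutually exclusive categories spanning every
    chapter: common cancers kept singular, dementias pooled across chapters
    (F00-F03 with G30), injury mechanisms pooled with injury natures, and a
    terminal category for U and Z codes that are not valid underlying causes.
    The grouping is a best-effort condensed list and is user-replaceable via
    :meth:`CategoryMapping.from_file`.
    """
    with resources.as_file(
        resources.files("multicause.data").joinpath("categories40.csv")
    ) as path:
        mapping = CategoryMapping.from_file(path)
    if len(mapping.categories) != 40:
        raise MappingError("shipped default mapping must define exactly 40 categories")
    return mapping
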