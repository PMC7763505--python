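"""ICD-9 code hierarchy: chapters, blocks, categories, and match criteria.

ICD-9 organises diagnoses in four nested levels.  The three-digit *category*
(four characters for E-codes, e.g. ``E950``) names the disease; optional
fourth/fifth digits after the decimal point refine it into a *full code*
(``518.81``).  Categories group into *blocks* (``510-519``), blocks into
*chapters* (17 disease chapters covering 001-999 plus the E and V
supplementary classifications).  A predicted code can agree with the true
code at any of these levels; the :class:`MatchLevel` enum orders the four
match criteria from the most general (CHAPTER) to the most rigorous (FULL).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path

__all__ = [
    "MatchLevel",
    "ChapterEntry",
    "BlockEntry",
    "HierarchyTable",
    "ICD9Components",
    "HierarchyError",
    "HierarchyValidationError",
    "ICD9ParseError",
    "load_hierarchy",
    "parse_code",
    "matches_at",
    "match_level",
]


class HierarchyError(ValueError):
    """Base class for hierarchy-table and code-parsing failures."""


class HierarchyValidationError(HierarchyError):
    """A hierarchy resource violates a structural invariant."""


class ICD9ParseError(HierarchyError):
    """A code string cannot be resolved against the hierarchy table."""


class MatchLevel(IntEnum):
    """The four match criteria, ordered general -> rigorous."""

    CHAPTER = 1
    BLOCK = 2
    CATEGORY = 3
    FULL = 4

    @property
    def display_name(self) -> str:
        return _LEVEL_NAMES[self]


_LEVEL_NAMES = {
    MatchLevel.CHAPTER: "Chapter Match",
    MatchLevel.BLOCK: "Block Match",
    MatchLevel.CATEGORY: "Three-Digit Category Match",
    MatchLevel.FULL: "Full Code Match",
}

# A category sorts into one of three namespaces: disease codes (001-999),
# V codes, and E codes.  Ranges never cross namespaces.
_KIND_DISEASE = ""
_CODE_RE = re.compile(r"^(\d{3}|E\d{3}|V\d{2})(?:\.(\d{1,2}))?$")


def _category_key(category: str) -> tuple[str, int]:
    """Map a category string to a (namespace, numeric) sort key."""
    if category.startswith("E"):
        return ("E", int(category[1:]))
    if category.startswith("V"):
        return ("V", int(category[1:]))
    return (_KIND_DISEASE, int(category))


@dataclass(frozen=True)
class ChapterEntry:
    chapter_id: int | str  # 1..17 for disease chapters, "E"/"V" supplementary
    label: str
    start: str
    end: str

    @property
    def is_supplementary(self) -> bool:
        return isinstance(self.chapter_id, str)


@dataclass(frozen=True)
class BlockEntry:
    block_id: str  # e.g. "510-519"
    label: str
    start: str
    end: str
    parent_chapter: int | str


@dataclass(frozen=True)
class ICD9Components:
    """A parsed ICD-9 code with its projections at every hierarchy level."""

    raw: str
    category: str
    subcategory: str
    chapter_id: int | str
    block_id: str

    @property
    def full_code(self) -> str:
        if self.subcategory:
            return f"{self.category}.{self.subcategory}"
        return self.category

    def at_level(self, level: MatchLevel) -> str:
        """Group label of this code at the given match level."""
        if level is MatchLevel.CHAPTER:
            return str(self.chapter_id)
        if level is MatchLevel.BLOCK:
            return self.block_id
        if level is MatchLevel.CATEGORY:
            return self.category
        return self.full_code


@dataclass
class HierarchyTable:
    """Validated chapter/block ranges plus fast range-lookup indices."""

    chapters: list[ChapterEntry]
    blocks: list[BlockEntry]
    supplementary: list[ChapterEntry]

    _chapter_index: dict[str, tuple[list[int], list[ChapterEntry]]] = field(
        default_factory=dict, repr=False
    )
    _block_index: dict[str, tuple[list[int], list[BlockEntry]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._build_indices()

    def _build_indices(self) -> None:
        self._chapter_index = {}
        self._block_index = {}
        by_kind: dict[str, list[ChapterEntry]] = {}
        for ch in [*self.chapters, *self.supplementary]:
            by_kind.setdefault(_category_key(ch.start)[0], []).append(ch)
        for kind, entries in by_kind.items():
            entries = sorted(entries, key=lambda e: _category_key(e.start)[1])
            self._chapter_index[kind] = ([_category_key(e.start)[1] for e in entries], entries)
        blocks_by_kind: dict[str, list[BlockEntry]] = {}
        for bl in self.blocks:
            blocks_by_kind.setdefault(_category_key(bl.start)[0], []).append(bl)
        for kind, entries in blocks_by_kind.items():
            entries = sorted(entries, key=lambda e: _category_key(e.start)[1])
            self._block_index[kind] = ([_category_key(e.start)[1] for e in entries], entries)

    def chapter_of(self, category: str) -> ChapterEntry:
        kind, num = _category_key(category)
        starts, entries = self._chapter_index.get(kind, ([], []))
        i = bisect_right(starts, num) - 1
        if i >= 0 and num <= _category_key(entries[i].end)[1]:
            return entries[i]
        raise ICD9ParseError(f"category {category!r} is outside every chapter range")

    def block_of(self, category: str) -> BlockEntry:
        kind, num = _category_key(category)
        starts, entries = self._block_index.get(kind, ([], []))
        i = bisect_right(starts, num) - 1
        if i >= 0 and num <= _category_key(entries[i].end)[1]:
            return entries[i]
        raise ICD9ParseError(f"category {category!r} is outside every block range")

    @property
    def n_disease_chapters(self) -> int:
        return len(self.chapters)

    @property
    def n_supplementary(self) -> int:
        return len(self.supplementary)

    @property
    def n_disease_blocks(self) -> int:
        return sum(1 for b in self.blocks if _category_key(b.start)[0] == _KIND_DISEASE)


def _validate_range(start: str, end: str, entry: str) -> None:
    for s in (start, end):
        if not re.match(r"^(\d{3}|E\d{3}|V\d{2})$", s):
            raise HierarchyValidationError(f"{entry}: malformed range bound {s!r}")
    ks, ke = _category_key(start), _category_key(end)
    if ks[0] != ke[0] or ks[1] > ke[1]:
        raise HierarchyValidationError(f"{entry}: invalid range {start}-{end}")


def _check_disjoint(entries, describe) -> None:
    by_kind: dict[str, list] = {}
    for e in entries:
        by_kind.setdefault(_category_key(e.start)[0], []).append(e)
    for kind, es in by_kind.items():
        es = sorted(es, key=lambda e: _category_key(e.start)[1])
        for a, b in zip(es, es[1:]):
            if _category_key(b.start)[1] <= _category_key(a.end)[1]:
                raise HierarchyValidationError(
                    f"overlapping ranges: {describe(a)} ({a.start}-{a.end}) and "
                    f"{describe(b)} ({b.start}-{b.end})"
                )


def _validate_table(table: HierarchyTable) -> None:
    if table.n_disease_chapters != 17:
        raise HierarchyValidationError(
            f"expected 17 disease chapters, found {table.n_disease_chapters}"
        )
    if table.n_supplementary != 2:
        raise HierarchyValidationError(
            f"expected 2 supplementary classifications, found {table.n_supplementary}"
        )
    if table.n_disease_blocks != 135:
        raise HierarchyValidationError(
            f"expected 135 disease blocks, found {table.n_disease_blocks}"
        )
    _check_disjoint([*table.chapters, *table.supplementary], lambda c: f"chapter {c.chapter_id}")
    _check_disjoint(table.blocks, lambda b: f"block {b.block_id}")
    # Disease chapters must cover 001-999 without gaps.
    disease = sorted(table.chapters, key=lambda c: int(c.start))
    if int(disease[0].start) != 1 or int(disease[-1].end) != 999:
        raise HierarchyValidationError("disease chapters do not span 001-999")
    for a, b in zip(disease, disease[1:]):
        if int(b.start) != int(a.end) + 1:
            raise HierarchyValidationError(
                f"gap between chapter {a.chapter_id} (ends {a.end}) and "
                f"chapter {b.chapter_id} (starts {b.start})"
            )
    # Every block must lie inside exactly one chapter of its namespace.
    for bl in table.blocks:
        try:
            ch_start = table.chapter_of(bl.start)
            ch_end = table.chapter_of(bl.end)
        except ICD9ParseError as exc:
            raise HierarchyValidationError(
                f"block {bl.block_id} lies outside every chapter: {exc}"
            ) from exc
        if ch_start is not ch_end or ch_start.chapter_id != bl.parent_chapter:
            raise HierarchyValidationError(
                f"block {bl.block_id} does not lie inside a single chapter"
            )


def _validate_table_relaxed(table: HierarchyTable) -> None:
    """Structural checks that apply to user-supplied partial tables too."""
    _check_disjoint([*table.chapters, *table.supplementary], lambda c: f"chapter {c.chapter_id}")
    _check_disjoint(table.blocks, lambda b: f"block {b.block_id}")
    for bl in table.blocks:
        try:
            ch_start = table.chapter_of(bl.start)
            ch_end = table.chapter_of(bl.end)
        except ICD9ParseError as exc:
            raise HierarchyValidationError(
                f"block {bl.block_id} lies outside every chapter: {exc}"
            ) from exc
        if ch_start is not ch_end or ch_start.chapter_id != bl.parent_chapter:
            raise HierarchyValidationError(
                f"block {bl.block_id} does not lie inside a single chapter"
            )


def load_hierarchy(resource_path: str | Path | None = None, *, strict: bool | None = None) -> HierarchyTable:
    """Load and validate a chapter/block table.

    Parameters
    ----------
    resource_path
        Tab-delimited table with columns ``kind, id, label, range_start,
        range_end`` (``kind`` in chapter/block/supplementary).  ``None``
        loads the bundled standard ICD-9 layout.
    strict
        Enforce the full 17-chapter / 2-supplementary / 135-block layout.
        Defaults to True for the bundled resource and False for user tables
        (which may be partial); structural invariants (disjoint ranges,
        blocks nested in chapters) are always enforced.
    """
    if resource_path is None:
        ref = resources.files("notecode.data").joinpath("icd9_hierarchy.tsv")
        text = ref.read_text(encoding="utf-8")
        if strict is None:
            strict = True
    else:
        path = Path(resource_path)
        if not path.exists():
            raise HierarchyError(f"hierarchy resource not found: {path}")
        text = path.read_text(encoding="utf-8")
        if strict is None:
            strict = False

    chapters: list[ChapterEntry] = []
    blocks: list[tuple[str, str, str, str]] = []
    supplementary: list[ChapterEntry] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise HierarchyValidationError(f"line {lineno}: expected 5 columns, got {len(parts)}")
        kind, entry_id, label, start, end = (p.strip() for p in parts)
        _validate_range(start, end, f"line {lineno} ({entry_id})")
        if kind == "chapter":
            chapters.append(ChapterEntry(int(entry_id), label, start, end))
        elif kind == "supplementary":
            supplementary.append(ChapterEntry(entry_id, label, start, end))
        elif kind == "block":
            blocks.append((entry_id, label, start, end))
        else:
            raise HierarchyValidationError(f"line {lineno}: unknown kind {kind!r}")

    # Resolve block parent chapters by range containment.
    probe = HierarchyTable(chapters=chapters, blocks=[], supplementary=supplementary)
    block_entries: list[BlockEntry] = []
    for entry_id, label, start, end in blocks:
        try:
            parent = probe.chapter_of(start).chapter_id
        except ICD9ParseError as exc:
            raise HierarchyValidationError(
                f"block {entry_id} lies outside every chapter: {exc}"
            ) from exc
        block_entries.append(BlockEntry(entry_id, label, start, end, parent))

    table = HierarchyTable(chapters=chapters, blocks=block_entries, supplementary=supplementary)
    if strict:
        _validate_table(table)
    else:
        _validate_table_relaxed(table)
    return table


def parse_code(code: str, table: HierarchyTable) -> ICD9Components:
    """Parse an ICD-9 code string into its hierarchy components.

    Codes are treated as normalized strings, never numbers, so trailing
    zeros are significant (``"410.0"`` differs from ``"410"``).  E-codes
    take a four-character category (``E950``), V-codes a three-character
    one (``V30``).  Categories absent from the table raise
    :class:`ICD9ParseError` rather than guessing a chapter.
    """
    raw = code
    norm = code.strip().upper()
    m = _CODE_RE.match(norm)
    if not m:
        raise ICD9ParseError(f"unparseable ICD-9 code: {raw!r}")
    category, subcategory = m.group(1), m.group(2) or ""
    chapter = table.chapter_of(category)
    block = table.block_of(category)
    return ICD9Components(
        raw=raw,
        category=category,
        subcategory=subcategory,
        chapter_id=chapter.chapter_id,
        block_id=block.block_id,
    )


def matches_at(predicted: ICD9Components, actual: ICD9Components, level: MatchLevel) -> bool:
    """Do two codes agree at the given hierarchy level?

    Symmetric in its code arguments; agreement at a rigorous level implies
    agreement at every more general one.
    """
    return predicted.at_level(level) == actual.at_level(level)


def match_level(predicted: ICD9Components, actual: ICD9Components) -> MatchLevel | None:
    """Finest level at which the two codes agree, or None if even the
    chapters differ."""
    finest: MatchLevel | None = None
    for level in MatchLevel:
        if matches_at(predicted, actual, level):
            finest = level
        else:
            break
    return finest
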