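"""Knowledge resources for measurement-value pair extraction.

The extractor is driven entirely by curated tables: a concept inventory of
27 standardized echocardiographic measurement concepts, a term dictionary
mapping surface strings to concepts, a word lexicon assigning anatomy /
measure semantic groups to single words, mutual-exclusion constraint pairs
between those groups, a unit table, and an ordered qualitative-grade
lexicon.  All tables are plain UTF-8 comma-delimited files with ``#``
comment lines, so that curation stays a text-editing task.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class LexiconError(ValueError):
    """Base class for resource-file problems."""


class ParseError(LexiconError):
    """A line of a resource file is syntactically malformed."""


class ResourceError(LexiconError):
    """A resource file is well-formed but internally inconsistent."""


class ValueKind(str, Enum):
    QUANTITATIVE = "QUANTITATIVE"
    QUALITATIVE = "QUALITATIVE"
    BOTH = "BOTH"

    def accepts_quantitative(self) -> bool:
        return self is not ValueKind.QUALITATIVE

    def accepts_qualitative(self) -> bool:
        return self is not ValueKind.QUANTITATIVE


class WordCategory(str, Enum):
    ANATOMY = "ANATOMY"
    MEASURE = "MEASURE"


_WS_RE = re.compile(r"\s+")
_SLASH_WS_RE = re.compile(r"\s*/\s*")


def normalize_surface(s: str) -> str:
    """Canonical form used for every dictionary comparison.

    Lower-case, leading/trailing whitespace stripped, internal whitespace
    collapsed to single spaces, and spaces around ``/`` removed so that
    "E / e'" and "e/e'" share one normal form.
    """
    s = _WS_RE.sub(" ", s.strip().lower())
    return _SLASH_WS_RE.sub("/", s)


@dataclass(frozen=True)
class Concept:
    concept_id: str
    label: str
    value_kind: ValueKind
    compatible_units: frozenset[str] = frozenset()
    anatomy_tags: frozenset[str] = frozenset()
    measure_tags: frozenset[str] = frozenset()

    @property
    def tags(self) -> frozenset[str]:
        return self.anatomy_tags | self.measure_tags


@dataclass(frozen=True)
class TermEntry:
    surface: str
    concept_id: str
    line_number: int = 0


@dataclass(frozen=True)
class WordEntry:
    surface: str
    category: WordCategory
    group_id: str


class WordLexicon:
    """Single words with an anatomy/measure category and a semantic group."""

    def __init__(self, entries: Iterable[WordEntry]):
        self.entries: list[WordEntry] = list(entries)
        self._by_surface: dict[str, WordEntry] = {}
        for e in self.entries:
            prev = self._by_surface.get(e.surface)
            if prev is not None and (prev.category, prev.group_id) != (e.category, e.group_id):
                raise ResourceError(
                    f"word {e.surface!r} assigned to both "
                    f"{prev.category.value}/{prev.group_id} and {e.category.value}/{e.group_id}"
                )
            self._by_surface[e.surface] = e

    def lookup(self, surface: str) -> WordEntry | None:
        return self._by_surface.get(normalize_surface(surface))

    def surfaces(self) -> list[str]:
        return list(self._by_surface)

    def groups(self) -> set[str]:
        return {e.group_id for e in self.entries}

    def groups_in(self, normalized_surface: str) -> set[str]:
        """Semantic groups of lexicon words occurring in a normalized phrase."""
        found = set()
        for tok in re.findall(r"[a-z0-9']+(?:/[a-z0-9']+)*", normalized_surface):
            e = self._by_surface.get(tok)
            if e is not None:
                found.add(e.group_id)
            elif "/" in tok:
                for part in tok.split("/"):
                    pe = self._by_surface.get(part)
                    if pe is not None:
                        found.add(pe.group_id)
        return found

    def __len__(self) -> int:
        return len(self._by_surface)


class ConstraintSet:
    """Unordered mutual-exclusion pairs between semantic groups."""

    def __init__(self, exclusions: Iterable[tuple[str, str]]):
        self.exclusions: set[frozenset[str]] = set()
        for a, b in exclusions:
            if a == b:
                raise ResourceError(f"group {a!r} declared exclusive with itself")
            self.exclusions.add(frozenset((a, b)))

    def excluded_by(self, group: str) -> set[str]:
        out = set()
        for pair in self.exclusions:
            if group in pair:
                out |= pair - {group}
        return out

    def excluded_by_any(self, groups: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for g in groups:
            out |= self.excluded_by(g)
        return out

    def pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted(p)) for p in self.exclusions}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self.exclusions

    def __len__(self) -> int:
        return len(self.exclusions)


@dataclass(frozen=True)
class Unit:
    unit_id: str
    dimension: str
    variants: tuple[str, ...]


class UnitTable:
    def __init__(self, units: Iterable[Unit]):
        self.units: list[Unit] = list(units)
        self._by_surface: dict[str, str] = {}
        for u in self.units:
            for v in u.variants:
                nv = normalize_surface(v)
                if nv in self._by_surface and self._by_surface[nv] != u.unit_id:
                    raise ResourceError(
                        f"unit surface {v!r} claimed by both "
                        f"{self._by_surface[nv]!r} and {u.unit_id!r}"
                    )
                self._by_surface[nv] = u.unit_id

    def lookup(self, surface: str) -> str | None:
        return self._by_surface.get(normalize_surface(surface))

    def surfaces(self) -> list[str]:
        return list(self._by_surface)

    def ids(self) -> set[str]:
        return {u.unit_id for u in self.units}

    def __len__(self) -> int:
        return len(self.units)


class QualLexicon:
    """Qualitative grade words with an integer severity rank."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self.entries: list[tuple[str, int]] = []
        self._rank: dict[str, int] = {}
        for surface, rank in entries:
            ns = normalize_surface(surface)
            if ns in self._rank and self._rank[ns] != rank:
                raise ResourceError(f"grade {surface!r} given two ranks")
            if ns not in self._rank:
                self.entries.append((ns, int(rank)))
            self._rank[ns] = int(rank)

    def rank_of(self, surface: str) -> int | None:
        return self._rank.get(normalize_surface(surface))

    def surfaces(self) -> list[str]:
        return [s for s, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# file readers


def _read_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    """Rows of a comma-delimited resource file, with 1-based line numbers.

    ``#`` comment lines and blank lines are skipped; quoting is honored so a
    surface may itself contain a comma.
    """
    rows: list[tuple[int, list[str]]] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parsed = next(csv.reader(io.StringIO(raw)))
        rows.append((lineno, [c.strip() for c in parsed]))
    return rows


def _split_multi(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in cell.split(";") if x.strip())


def load_concepts(path: str | Path) -> list[Concept]:
    """Read ``concepts.csv``: concept_id,label,value_kind,units,anatomy,measure."""
    concepts: list[Concept] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path):
        if len(row) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
        cid, label, kind, units, anat, meas = row
        try:
            vk = ValueKind(kind)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: unknown value kind {kind!r}") from exc
        if cid in seen:
            raise ResourceError(f"{path}:{lineno}: duplicate concept_id {cid!r}")
        seen.add(cid)
        concepts.append(
            Concept(cid, label, vk, _split_multi(units), _split_multi(anat), _split_multi(meas))
        )
    return concepts


def load_dictionary(
    path: str | Path, concepts: Sequence[Concept] | None = None
) -> tuple[list[TermEntry], list[Concept]]:
    """Read the term dictionary: one ``term,concept_id`` pair per line.

    Surfaces are normalized on load; a surface mapping to two different
    concepts is a resource error (ambiguity is the mapper's job, not the
    dictionary's).  When *concepts* is omitted the shipped inventory is used.
    """
    if concepts is None:
        from .resources import default_resource_path

        concepts = load_concepts(default_resource_path("concepts.csv"))
    known = {c.concept_id for c in concepts}
    entries: list[TermEntry] = []
    by_surface: dict[str, TermEntry] = {}
    for lineno, row in _read_rows(path):
        if len(row) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
        surface, cid = normalize_surface(row[0]), row[1]
        if not surface:
            raise ParseError(f"{path}:{lineno}: empty term surface")
        if cid not in known:
            raise ResourceError(f"{path}:{lineno}: unknown concept_id {cid!r}")
        prev = by_surface.get(surface)
        if prev is not None:
            if prev.concept_id != cid:
                raise ResourceError(
                    f"{path}:{lineno}: surface {surface!r} maps to both "
                    f"{prev.concept_id!r} (line {prev.line_number}) and {cid!r}"
                )
            continue
        entry = TermEntry(surface, cid, lineno)
        by_surface[surface] = entry
        entries.append(entry)
    return entries, list(concepts)


def load_word_lexicon(path: str | Path) -> WordLexicon:
    """Read ``words.csv``: surface,category,group_id."""
    entries: list[WordEntry] = []
    for lineno, row in _read_rows(path):
        if len(row) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
        surface, category, group = row
        try:
            cat = WordCategory(category)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: category must be ANATOMY or MEASURE, got {category!r}") from exc
        entries.append(WordEntry(normalize_surface(surface), cat, group))
    return WordLexicon(entries)


def load_constraints(path: str | Path) -> ConstraintSet:
    pairs = []
    for lineno, row in _read_rows(path):
        if len(row) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
        pairs.append((row[0], row[1]))
    return ConstraintSet(pairs)


def load_units(path: str | Path) -> UnitTable:
    units = []
    for lineno, row in _read_rows(path):
        if len(row) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
        unit_id, dimension, variants = row
        units.append(Unit(unit_id, dimension, tuple(v.strip() for v in variants.split(";") if v.strip())))
    return UnitTable(units)


def load_qualitative(path: str | Path) -> QualLexicon:
    entries = []
    for lineno, row in _read_rows(path):
        if len(row) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
        try:
            rank = int(row[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: rank must be an integer, got {row[1]!r}") from exc
        entries.append((row[0], rank))
    return QualLexicon(entries)


# ---------------------------------------------------------------------------
# serialization (round-trip support for curation tooling)


def dump_dictionary(entries: Sequence[TermEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        for e in entries:
            writer.writerow([e.surface, e.concept_id])


# ---------------------------------------------------------------------------
# cross-resource validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    infos: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_resources(
    entries: Sequence[TermEntry],
    concepts: Sequence[Concept],
    lexicon: WordLexicon,
    constraints: ConstraintSet,
    units: UnitTable,
) -> ValidationReport:
    """Cross-check the loaded tables; errors make the bundle unusable."""
    report = ValidationReport()
    known_groups = lexicon.groups()
    unit_ids = units.ids()

    covered = {e.concept_id for e in entries}
    for c in concepts:
        if c.concept_id not in covered:
            report.warnings.append(f"concept {c.concept_id!r} has no dictionary terms")
        for uid in c.compatible_units:
            if uid not in unit_ids:
                report.errors.append(
                    f"concept {c.concept_id!r} references unknown unit {uid!r}"
                )

    for e in entries:
        for tok in e.surface.split():
            if tok not in {"of", "the", "at", "a", "an", "to", "and"} and lexicon.lookup(tok) is None:
                report.infos.append(
                    f"dictionary surface {e.surface!r}: word {tok!r} not in word lexicon"
                )

    for a, b in sorted(constraints.pairs()):
        for g in (a, b):
            if g not in known_groups:
                report.errors.append(f"constraint pair ({a}, {b}) references unknown group {g!r}")
    return report
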