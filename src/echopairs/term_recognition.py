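"""Locating candidate measurement terms in document text.

Three recognizers contribute candidates: complete-phrase matches against the
term dictionary, abbreviation regexes, and the concept builder, which merges
consecutive anatomy/measure words (e.g. "dimension of the left ventricle at
the end of diastole") into new candidate terms that need not appear in the
dictionary verbatim.  Overlapping candidates are resolved longest-first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .lexicon import TermEntry, WordCategory, WordLexicon, normalize_surface

#: connectors allowed between words merged by the concept builder
CONNECTOR_WORDS = frozenset({"of", "the", "at", "a", "an"})
#: longest run of categorized words a built term may cover
MAX_BUILT_WORDS = 8


@dataclass(frozen=True)
class Span:
    start: int
    end: int
    text: str

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


def make_span(text: str, start: int, end: int) -> Span:
    if not (0 <= start < end <= len(text)):
        raise ValueError(f"invalid span [{start}, {end}) for document of length {len(text)}")
    return Span(start, end, text[start:end])


@dataclass(frozen=True)
class WordMention:
    span: Span
    category: WordCategory
    group_id: str


class TermOrigin(str, Enum):
    PHRASE = "PHRASE"
    ABBREVIATION = "ABBREVIATION"
    BUILT = "BUILT"


#: tie-break priority for overlap resolution (higher wins)
_ORIGIN_PRIORITY = {TermOrigin.PHRASE: 2, TermOrigin.ABBREVIATION: 1, TermOrigin.BUILT: 0}


@dataclass(frozen=True)
class TermMention:
    span: Span
    normalized_surface: str
    origin: TermOrigin
    candidates: tuple[tuple[str, int], ...] = ()
    mapped_concept: str | None = None  # concept_id, or None (unmapped/ambiguous)
    ambiguous: bool = False


_BOUNDARY_L = r"(?<![A-Za-z0-9])"
_BOUNDARY_R = r"(?![A-Za-z0-9])"


def _surface_to_pattern(surface: str) -> str:
    """Regex for one normalized surface, tolerant of whitespace/hyphen runs."""
    tokens = surface.split(" ")
    parts = []
    for tok in tokens:
        # '/' joins sub-tokens that may also be spaced in text ("e / e'")
        if "/" in tok and len(tok) > 1:
            sub = [re.escape(s) for s in tok.split("/")]
            parts.append(r"[ \t]*/[ \t]*".join(sub))
        else:
            parts.append(re.escape(tok))
    # terms never span a line break: the line is the semi-structured unit
    return r"[ \t\-]+".join(parts)


def _compile_alternation(surfaces: Iterable[str]) -> re.Pattern | None:
    ordered = sorted(set(surfaces), key=len, reverse=True)
    if not ordered:
        return None
    body = "|".join(_surface_to_pattern(s) for s in ordered)
    return re.compile(f"{_BOUNDARY_L}(?:{body}){_BOUNDARY_R}", re.IGNORECASE)


def find_phrase_terms(
    text: str,
    entries: Sequence[TermEntry],
    abbreviations: Sequence[str] | Sequence[re.Pattern] = (),
) -> list[TermMention]:
    """Complete-phrase and abbreviation matches at token boundaries.

    A span matched by both a dictionary surface and an abbreviation pattern
    is reported once, as an ABBREVIATION.  Matches never start or end inside
    a longer alphanumeric run ("relief" does not contain the term "ef").
    """
    found: dict[tuple[int, int], TermMention] = {}

    dict_re = _compile_alternation(e.surface for e in entries)
    if dict_re is not None:
        for m in dict_re.finditer(text):
            span = make_span(text, m.start(), m.end())
            found[(span.start, span.end)] = TermMention(
                span, normalize_surface(span.text), TermOrigin.PHRASE
            )

    for pat in abbreviations:
        if isinstance(pat, str):
            pat = re.compile(f"{_BOUNDARY_L}(?:{pat}){_BOUNDARY_R}", re.IGNORECASE)
        for m in pat.finditer(text):
            span = make_span(text, m.start(), m.end())
            found[(span.start, span.end)] = TermMention(
                span, normalize_surface(span.text), TermOrigin.ABBREVIATION
            )

    return sorted(found.values(), key=lambda t: (t.span.start, t.span.end))


def find_category_words(text: str, lexicon: WordLexicon) -> list[WordMention]:
    """Boundary-respecting occurrences of anatomy/measure words, longest-first."""
    word_re = _compile_alternation(lexicon.surfaces())
    if word_re is None:
        return []
    out = []
    for m in word_re.finditer(text):
        entry = lexicon.lookup(m.group(0))
        if entry is None:  # pragma: no cover - alternation only matches surfaces
            continue
        out.append(WordMention(make_span(text, m.start(), m.end()), entry.category, entry.group_id))
    return out


_CONNECTOR_CHARS_RE = re.compile(r"[^\W_]+", re.UNICODE)


def _is_connector_gap(gap: str) -> bool:
    """Gap text between merged words: whitespace / hyphen / slash plus
    a small closed class of function words; never a line break."""
    if "\n" in gap:
        return False
    if not re.fullmatch(r"[A-Za-z\s\-/]*", gap):
        return False
    words = re.findall(r"[A-Za-z]+", gap.lower())
    return all(w in CONNECTOR_WORDS for w in words)


def build_candidate_terms(words: Sequence[WordMention], text: str) -> list[TermMention]:
    """The concept builder: merge consecutive anatomy/measure words.

    Maximal runs whose members are separated only by connectors become one
    BUILT mention; a run must mix both categories (>=1 ANATOMY and >=1
    MEASURE) and stay within MAX_BUILT_WORDS words.
    """
    words = sorted(words, key=lambda w: (w.span.start, w.span.end))
    mentions: list[TermMention] = []
    i = 0
    while i < len(words):
        run = [words[i]]
        j = i
        while j + 1 < len(words) and len(run) < MAX_BUILT_WORDS:
            gap = text[words[j].span.end : words[j + 1].span.start]
            if words[j + 1].span.start < words[j].span.end or not _is_connector_gap(gap):
                break
            run.append(words[j + 1])
            j += 1
        cats = {w.category for w in run}
        if len(run) >= 2 and cats == {WordCategory.ANATOMY, WordCategory.MEASURE}:
            span = make_span(text, run[0].span.start, run[-1].span.end)
            mentions.append(
                TermMention(span, normalize_surface(span.text), TermOrigin.BUILT)
            )
        i = j + 1
    return mentions


def resolve_overlaps(mentions: Sequence[TermMention]) -> list[TermMention]:
    """Keep a non-overlapping subset: longest span wins; ties broken by
    origin priority (PHRASE > ABBREVIATION > BUILT), then leftmost.

    Deterministic regardless of input order.
    """
    ranked = sorted(
        mentions,
        key=lambda t: (
            -len(t.span),
            -_ORIGIN_PRIORITY[t.origin],
            t.span.start,
            t.normalized_surface,
        ),
    )
    kept: list[TermMention] = []
    for cand in ranked:
        if not any(cand.span.overlaps(k.span) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda t: t.span.start)
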