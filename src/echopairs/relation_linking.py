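"""Linking mapped measurement terms to values via co-occurrence patterns.

Echocardiogram reporting is a sublanguage: a small number of recurring slot
sequences (term, separating string, value, unit) account for nearly all
measurement statements, whether tabulated ("LVEF = 40%", "LVEDD: 16mm") or
narrative ("Ejection fraction was 40%", "mild aortic stenosis").  Each
licensed sequence is a PatternRule, loaded from a config file so curation
can adjust rules without touching code.  Rules are applied in priority
order; a mention participates in at most one extracted pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Sequence

from .concept_mapping import MappingStatus, map_term
from .lexicon import Concept, _read_rows
from .term_recognition import (
    Span,
    TermMention,
    WordMention,
    _is_connector_gap,
    build_candidate_terms,
    find_category_words,
    find_phrase_terms,
    make_span,
    resolve_overlaps,
)
from .value_recognition import (
    UnitMention,
    ValueMention,
    ValueMentionKind,
    find_qualitative_values,
    find_quantitative_values,
    find_units,
)

logger = logging.getLogger(__name__)

_VERB_SEP = (
    r"\s+(?:(?:is|was|are|were|appears?|remains?|measures?)"
    r"(?:\s+(?:visually|currently|now))?"
    r"(?:\s+(?:estimated|measured|calculated|noted|assessed))?"
    r"(?:\s+(?:at|to\s+be|in\s+a\s+range\s+of))?"
    r"|measured\s+at|estimated\s+(?:at|in\s+a\s+range\s+of))\s+"
)

#: separator classes a rule may name; each is matched against the whole
#: stretch of text between the two slots
SEPARATOR_CLASSES: dict[str, str] = {
    "equals": r"\s*=\s*",
    "colon": r"\s*:\s*",
    "column": r"[ \t]+",
    "verb": _VERB_SEP,
    "paren": r"\s*\(\s*",
    "adjacent": r"[ \t]+",
    "within": "",  # handled structurally, not by regex
}

_HEAD_GAP_RE = re.compile(r"\s+(?:has|have|had|with|shows?|showed|demonstrates?)\s+|\s+")

_VALID_SLOTS = ({"TERM", "SEP", "VALUE"}, {"TERM", "SEP", "VALUE", "UNIT"},
                {"VALUE", "TERM"}, {"TERM_HEAD", "VALUE", "TERM_TAIL"})


class PatternConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PatternRule:
    rule_id: str
    priority: int
    slots: tuple[str, ...]
    separator_class: str
    max_gap: int
    scope: str  # LINE | SENTENCE
    value_kind: ValueMentionKind
    value_form: str  # point | range
    unit_mode: str  # attached | detached | none | any

    def __post_init__(self):
        if set(self.slots) not in _VALID_SLOTS or self.slots.count("TERM") > 1:
            raise PatternConfigError(f"rule {self.rule_id}: bad slot sequence {self.slots}")
        if self.slots.count("VALUE") != 1:
            raise PatternConfigError(f"rule {self.rule_id}: exactly one VALUE slot required")
        if self.separator_class not in SEPARATOR_CLASSES:
            raise PatternConfigError(
                f"rule {self.rule_id}: unknown separator class {self.separator_class!r}"
            )
        if self.max_gap < 0:
            raise PatternConfigError(f"rule {self.rule_id}: max_gap must be >= 0")
        if self.scope not in ("LINE", "SENTENCE"):
            raise PatternConfigError(f"rule {self.rule_id}: scope must be LINE or SENTENCE")


@dataclass(frozen=True)
class MeasurementValuePair:
    doc_id: str
    concept_id: str
    term_span: Span
    value: ValueMention
    unit_id: str | None
    rule_id: str
    line_number: int
    unit_compatible: bool | None = None  # None: no unit or concept has no unit list


def load_patterns(path) -> list[PatternRule]:
    """Read the pattern config; rules come back sorted by priority."""
    rules: list[PatternRule] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path):
        if len(row) != 9:
            raise PatternConfigError(f"{path}:{lineno}: expected 9 fields, got {len(row)}")
        rule_id, priority, slots, sep, max_gap, scope, kind, form, unit_mode = row
        if rule_id in seen:
            raise PatternConfigError(f"{path}:{lineno}: duplicate rule_id {rule_id!r}")
        seen.add(rule_id)
        try:
            rules.append(
                PatternRule(
                    rule_id,
                    int(priority),
                    tuple(slots.split()),
                    sep,
                    int(max_gap),
                    scope,
                    ValueMentionKind(kind),
                    form,
                    unit_mode,
                )
            )
        except ValueError as exc:
            raise PatternConfigError(f"{path}:{lineno}: {exc}") from exc
    if not rules:
        logger.warning("pattern config %s contains no rules", path)
    return sorted(rules, key=lambda r: r.priority)


# ---------------------------------------------------------------------------
# window segmentation


def line_windows(text: str) -> list[tuple[int, int]]:
    out, pos = [], 0
    for line in text.split("\n"):
        out.append((pos, pos + len(line)))
        pos += len(line) + 1
    return out


_SENTENCE_BOUNDARY = re.compile(r"\.\s+|;\s*|\n+")


def sentence_windows(text: str) -> list[tuple[int, int]]:
    out, pos = [], 0
    for m in _SENTENCE_BOUNDARY.finditer(text):
        if m.start() > pos:
            out.append((pos, m.start()))
        pos = m.end()
    if pos < len(text):
        out.append((pos, len(text)))
    return out


# ---------------------------------------------------------------------------
# the matcher


def _kind_ok(concept: Concept, kind: ValueMentionKind) -> bool:
    if kind is ValueMentionKind.QUANT:
        return concept.value_kind.accepts_quantitative()
    return concept.value_kind.accepts_qualitative()


def _unit_flag(concept: Concept, unit_id: str | None) -> bool | None:
    if unit_id is None or not concept.compatible_units:
        return None
    return unit_id in concept.compatible_units


class _LinkState:
    """Mention pools plus consumption bookkeeping for one document."""

    def __init__(self, text, terms, values, units, words):
        self.text = text
        self.terms = sorted(terms, key=lambda t: t.span.start)
        self.values = sorted(values, key=lambda v: v.span.start)
        self.units = sorted(units, key=lambda u: u.span.start)
        self.words = sorted(words, key=lambda w: w.span.start)
        self.used_terms: set[int] = set()
        self.used_values: set[int] = set()
        self.used_units: set[int] = set()

    def free_terms(self, lo, hi):
        return [
            (i, t)
            for i, t in enumerate(self.terms)
            if i not in self.used_terms
            and lo <= t.span.start
            and t.span.end <= hi
            and t.mapped_concept is not None
        ]

    def free_values(self, lo, hi, kind, is_range):
        return [
            (i, v)
            for i, v in enumerate(self.values)
            if i not in self.used_values
            and lo <= v.span.start
            and v.span.end <= hi
            and v.kind == kind
            and v.is_range == is_range
        ]

    def term_between(self, lo, hi) -> bool:
        return any(
            i not in self.used_terms and lo < t.span.start and t.span.end <= hi
            for i, t in enumerate(self.terms)
            if t.mapped_concept is not None
        )


def link_measurement_values(
    text: str,
    terms: Sequence[TermMention],
    values: Sequence[ValueMention],
    units: Sequence[UnitMention],
    rules: Sequence[PatternRule],
    *,
    doc_id: str = "",
    concepts: dict[str, Concept] | None = None,
    words: Sequence[WordMention] = (),
    mapper=None,
    unit_mismatch: str = "warn",
) -> list[MeasurementValuePair]:
    """Apply the pattern rules in priority order and emit pairs.

    *mapper* is a callable ``surface -> MappingResult`` used only by the
    within-term rules (the head+tail of the split phrase is re-mapped as one
    concatenated candidate term).
    """
    concepts = concepts or {}
    state = _LinkState(text, terms, values, units, words)
    lines = line_windows(text)
    sentences = sentence_windows(text)
    pairs: list[MeasurementValuePair] = []

    for rule in sorted(rules, key=lambda r: r.priority):
        windows = lines if rule.scope == "LINE" else sentences
        for lo, hi in windows:
            if rule.slots[0] == "TERM_HEAD":
                pairs.extend(_match_within(rule, state, lo, hi, doc_id, concepts, mapper, unit_mismatch))
            elif rule.slots[0] == "VALUE":
                pairs.extend(_match_value_first(rule, state, lo, hi, doc_id, concepts, unit_mismatch))
            else:
                pairs.extend(_match_term_first(rule, state, lo, hi, doc_id, concepts, unit_mismatch))
    return sorted(pairs, key=lambda p: (p.term_span.start, p.value.span.start))


def _emit(state, rule, doc_id, concepts, unit_mismatch, term_span, concept_id, value, unit_id):
    concept = concepts.get(concept_id)
    flag = _unit_flag(concept, unit_id) if concept is not None else None
    if unit_mismatch == "drop" and flag is False:
        return None
    line_number = state.text.count("\n", 0, term_span.start) + 1
    return MeasurementValuePair(
        doc_id, concept_id, term_span, value, unit_id, rule.rule_id, line_number, flag
    )


def _sep_ok(rule: PatternRule, gap: str) -> bool:
    if len(gap) > rule.max_gap:
        return False
    return re.fullmatch(SEPARATOR_CLASSES[rule.separator_class], gap, re.IGNORECASE) is not None


def _match_term_first(rule, state, lo, hi, doc_id, concepts, unit_mismatch):
    out = []
    want_range = rule.value_form == "range"
    for ti, term in state.free_terms(lo, hi):
        concept = concepts.get(term.mapped_concept)
        if concept is not None and not _kind_ok(concept, rule.value_kind):
            continue
        after = [
            (vi, v)
            for vi, v in state.free_values(lo, hi, rule.value_kind, want_range)
            if v.span.start >= term.span.end
        ]
        if not after:
            continue
        vi, value = after[0]  # nearest value of the required shape
        gap = state.text[term.span.end : value.span.start]
        if not _sep_ok(rule, gap):
            continue
        if state.term_between(term.span.end, value.span.start):
            continue
        unit_id = value.unit_id
        used_unit = None
        if rule.unit_mode == "attached" and unit_id is None:
            continue
        if rule.unit_mode == "none" and unit_id is not None:
            continue
        if rule.unit_mode == "detached":
            if unit_id is not None:
                continue
            match = None
            for ui, u in enumerate(state.units):
                if ui in state.used_units or u.span.start < value.span.end or u.span.end > hi:
                    continue
                ugap = state.text[value.span.end : u.span.start]
                if len(ugap) <= 3 and ugap.strip() == "":
                    match = (ui, u)
                break
            if match is None:
                continue
            used_unit, unit_id = match[0], match[1].unit_id
        pair = _emit(
            state, rule, doc_id, concepts, unit_mismatch,
            term.span, term.mapped_concept, value, unit_id,
        )
        if pair is not None:
            out.append(pair)
            state.used_terms.add(ti)
            state.used_values.add(vi)
            if used_unit is not None:
                state.used_units.add(used_unit)
    return out


def _match_value_first(rule, state, lo, hi, doc_id, concepts, unit_mismatch):
    out = []
    want_range = rule.value_form == "range"
    for vi, value in state.free_values(lo, hi, rule.value_kind, want_range):
        after = [(ti, t) for ti, t in state.free_terms(lo, hi) if t.span.start >= value.span.end]
        if not after:
            continue
        ti, term = after[0]
        concept = concepts.get(term.mapped_concept)
        if concept is not None and not _kind_ok(concept, rule.value_kind):
            continue
        gap = state.text[value.span.end : term.span.start]
        if not _sep_ok(rule, gap):
            continue
        pair = _emit(
            state, rule, doc_id, concepts, unit_mismatch,
            term.span, term.mapped_concept, value, value.unit_id,
        )
        if pair is not None:
            out.append(pair)
            state.used_terms.add(ti)
            state.used_values.add(vi)
    return out


def _match_within(rule, state, lo, hi, doc_id, concepts, mapper, unit_mismatch):
    """TERM_HEAD VALUE TERM_TAIL: a qualitative grade splitting one term
    ("aortic valve has mild stenosis")."""
    if mapper is None:
        return []
    out = []
    want_range = rule.value_form == "range"
    window_words = [w for w in state.words if lo <= w.span.start and w.span.end <= hi]
    for vi, value in state.free_values(lo, hi, rule.value_kind, want_range):
        before = [w for w in window_words if w.span.end <= value.span.start]
        after = [w for w in window_words if w.span.start >= value.span.end]
        if not before or not after:
            continue
        head = [before[-1]]
        gap = state.text[head[0].span.end : value.span.start]
        if len(gap) > rule.max_gap or not _HEAD_GAP_RE.fullmatch(gap):
            continue
        for w in reversed(before[:-1]):
            g = state.text[w.span.end : head[0].span.start]
            if _is_connector_gap(g):
                head.insert(0, w)
            else:
                break
        tail = [after[0]]
        if not re.fullmatch(r"\s+", state.text[value.span.end : tail[0].span.start]):
            continue
        for w in after[1:]:
            g = state.text[tail[-1].span.end : w.span.start]
            if _is_connector_gap(g):
                tail.append(w)
            else:
                break
        surface = " ".join(w.span.text.lower() for w in head + tail)
        result = mapper(surface)
        if result.status is not MappingStatus.MAPPED:
            continue
        concept = concepts.get(result.concept_id)
        if concept is not None and not _kind_ok(concept, rule.value_kind):
            continue
        term_span = make_span(state.text, head[0].span.start, tail[-1].span.end)
        pair = _emit(
            state, rule, doc_id, concepts, unit_mismatch,
            term_span, result.concept_id, value, None,
        )
        if pair is not None:
            out.append(pair)
            state.used_values.add(vi)
    return out


# ---------------------------------------------------------------------------
# full pipeline for one document


def extract_document(doc, resources, *, unit_mismatch: str = "warn") -> list[MeasurementValuePair]:
    """Term recognition -> concept mapping -> value recognition -> linking."""
    text = getattr(doc, "text", doc)
    doc_id = getattr(doc, "doc_id", "")

    phrase = find_phrase_terms(text, resources.entries, resources.abbreviation_patterns)
    words = find_category_words(text, resources.lexicon)
    built = build_candidate_terms(words, text)
    mentions = resolve_overlaps(list(phrase) + list(built))

    mapped: list[TermMention] = []
    for m in mentions:
        result = map_term(
            m, resources.entries, resources.concept_map, resources.lexicon, resources.constraints
        )
        mapped.append(
            replace(
                m,
                candidates=tuple(result.scored),
                mapped_concept=result.concept_id,
                ambiguous=result.status is MappingStatus.AMBIGUOUS,
            )
        )

    quant = find_quantitative_values(text, resources.units)
    qual = find_qualitative_values(text, resources.qualitative)
    term_spans = [m.span for m in mapped if m.mapped_concept is not None]
    values = [
        v for v in quant + qual if not any(v.span.overlaps(s) for s in term_spans)
    ]
    unit_mentions = find_units(text, resources.units, exclude=values)

    def _mapper(surface: str):
        return map_term(
            surface, resources.entries, resources.concept_map, resources.lexicon, resources.constraints
        )

    return link_measurement_values(
        text,
        mapped,
        values,
        unit_mentions,
        resources.patterns,
        doc_id=doc_id,
        concepts=resources.concept_map,
        words=words,
        mapper=_mapper,
        unit_mismatch=unit_mismatch,
    )
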