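"""Two-step dictionary lookup with semantic-constraint disambiguation.

A recognized term is first looked up verbatim in the dictionary.  Failing
that, it is split into whitespace tokens and every concept is scored by the
number of distinct query tokens that appear in at least one of its
dictionary surfaces.  Mutual-exclusion constraints between anatomy/measure
word groups then discard incompatible candidates: a phrase containing
"atrial" cannot map to a ventricular, mitral or tricuspid concept, and a
phrase containing "volume" cannot map to a dimension, velocity or pressure
concept.  A strict maximum wins; a tie is ambiguous and yields no mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .lexicon import Concept, ConstraintSet, TermEntry, WordLexicon, normalize_surface
from .term_recognition import TermMention

#: connective words ignored by the token-overlap scorer
STOP_TOKENS = frozenset({"of", "the", "at", "a", "an", "to", "and"})


class MappingStatus(str, Enum):
    MAPPED = "MAPPED"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class MappingResult:
    status: MappingStatus
    concept_id: str | None = None
    scored: tuple[tuple[str, int], ...] = ()


def content_tokens(surface: str) -> list[str]:
    return [t for t in normalize_surface(surface).split() if t not in STOP_TOKENS]


def exact_match(surface: str, entries: Sequence[TermEntry]) -> str | None:
    surface = normalize_surface(surface)
    if not surface:
        return None
    for e in entries:
        if e.surface == surface:
            return e.concept_id
    return None


def token_overlap_scores(
    surface: str, entries: Sequence[TermEntry]
) -> list[tuple[str, int]]:
    """Score each concept by distinct query tokens found in its surfaces.

    Repeated query tokens count once; stop tokens are ignored; concepts with
    score zero are omitted.  Sorted by descending score, then concept_id for
    a stable order.
    """
    query = set(content_tokens(surface))
    if not query:
        return []
    concept_tokens: dict[str, set[str]] = {}
    for e in entries:
        concept_tokens.setdefault(e.concept_id, set()).update(e.surface.split())
    scores = []
    for cid, toks in concept_tokens.items():
        n = sum(1 for q in query if q in toks)
        if n > 0:
            scores.append((cid, n))
    scores.sort(key=lambda cs: (-cs[1], cs[0]))
    return scores


def apply_semantic_constraints(
    surface: str,
    scored: Sequence[tuple[str, int]],
    lexicon: WordLexicon,
    constraints: ConstraintSet,
    concepts: Mapping[str, Concept],
) -> list[tuple[str, int]]:
    """Drop candidates tagged with a group mutually exclusive with any
    lexicon-word group present in the query surface.  Scores are unchanged;
    the candidate set can only shrink."""
    groups_present = lexicon.groups_in(normalize_surface(surface))
    forbidden = constraints.excluded_by_any(groups_present)
    if not forbidden:
        return list(scored)
    out = []
    for cid, score in scored:
        concept = concepts.get(cid)
        tags = concept.tags if concept is not None else frozenset()
        if tags & forbidden:
            continue
        out.append((cid, score))
    return out


def map_term(
    mention: TermMention | str,
    entries: Sequence[TermEntry],
    concepts: Sequence[Concept] | Mapping[str, Concept],
    lexicon: WordLexicon,
    constraints: ConstraintSet,
) -> MappingResult:
    """Full two-step lookup for one term mention (or raw surface)."""
    if not isinstance(concepts, Mapping):
        concepts = {c.concept_id: c for c in concepts}
    surface = mention if isinstance(mention, str) else mention.normalized_surface

    exact = exact_match(surface, entries)
    if exact is not None:
        kept = apply_semantic_constraints(surface, [(exact, 1)], lexicon, constraints, concepts)
        if kept:
            return MappingResult(MappingStatus.MAPPED, exact, tuple(kept))
        return MappingResult(MappingStatus.UNMAPPED, None, ())

    scored = token_overlap_scores(surface, entries)
    kept = apply_semantic_constraints(surface, scored, lexicon, constraints, concepts)
    if not kept:
        return MappingResult(MappingStatus.UNMAPPED, None, tuple(kept))
    top = kept[0][1]
    winners = [cid for cid, s in kept if s == top]
    if len(winners) > 1:
        return MappingResult(MappingStatus.AMBIGUOUS, None, tuple(kept))
    return MappingResult(MappingStatus.MAPPED, winners[0], tuple(kept))
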