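"""Recognition of quantitative values, qualitative grades, units and ranges.

Quantitative values are decimals with an optionally attached unit ("40%",
"16mm", "2 cm"); qualitative values are graded severity words ("mild",
"moderate") drawn from an ordered lexicon.  Adjacent point values joined by
a range connector ("50-55", "50 to 55", "low to moderate") are merged into
a single range mention.  Context guards keep blood pressures, dates and
times ("120/80", "03/04/2015", "12:30") from being read as measurements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from .lexicon import QualLexicon, UnitTable
from .term_recognition import Span, make_span


class ValueMentionKind(str, Enum):
    QUANT = "QUANT"
    QUAL = "QUAL"


@dataclass(frozen=True)
class ValueMention:
    span: Span
    kind: ValueMentionKind
    low: float | int
    high: float | int
    low_text: str
    high_text: str
    unit_id: str | None = None
    is_range: bool = False


@dataclass(frozen=True)
class UnitMention:
    span: Span
    unit_id: str


_NUMBER_RE = re.compile(r"(?<![A-Za-z0-9.])\d+(?:\.\d+)?")
#: maximum characters between a number and its attached unit
UNIT_ATTACH_WINDOW = 2
#: connector between the two endpoints of a range
RANGE_CONNECTOR_RE = re.compile(r"\s*(?:-|–|—|to)\s*", re.IGNORECASE)


def _unit_variant_pattern(variant: str, attach: bool) -> str:
    body = r"\s+".join(re.escape(tok) for tok in variant.split())
    # in attach position ("16mm") the unit may butt against the digits, so
    # the left token boundary is only enforced for free-standing scans
    if not attach and variant and variant[0].isalnum():
        body = r"(?<![A-Za-z0-9])" + body
    if variant and variant[-1].isalnum():
        body = body + r"(?![A-Za-z0-9])"
    return body


def _compile_unit_alternation(units: UnitTable, attach: bool = False) -> re.Pattern | None:
    surfaces = sorted(units.surfaces(), key=len, reverse=True)
    if not surfaces:
        return None
    return re.compile(
        "|".join(f"(?:{_unit_variant_pattern(s, attach)})" for s in surfaces), re.IGNORECASE
    )


def _parse_number(text: str) -> float | int:
    return float(text) if "." in text else int(text)


def find_quantitative_values(text: str, units: UnitTable | None = None) -> list[ValueMention]:
    """Numbers with optional attached units, merged into ranges.

    A number taking part in a slash construct ("120/80", "03/04/15") or a
    clock time ("12:30") is not a standalone measurement value; a number
    running straight into letters that do not form a known unit ("40mg",
    "ICD10") is rejected by the token-boundary rule.
    """
    unit_re = _compile_unit_alternation(units, attach=True) if units is not None else None
    points: list[ValueMention] = []
    for m in _NUMBER_RE.finditer(text):
        start, end = m.start(), m.end()
        before = text[:start].rstrip()
        after = text[end:]
        # slash guard: fragment of a blood pressure, date, or fraction
        if before.endswith("/") and before[:-1].rstrip()[-1:].isdigit():
            continue
        if re.match(r"\s*/\s*\d", after):
            continue
        # clock-time guard
        if before.endswith(":") and before[:-1][-1:].isdigit():
            continue
        if re.match(r":\d", after):
            continue

        unit_id = None
        span_end = end
        if unit_re is not None:
            um = unit_re.match(text, pos=end)
            if um is None:
                gap = re.match(r"\s{1,%d}" % UNIT_ATTACH_WINDOW, after)
                if gap:
                    um = unit_re.match(text, pos=end + gap.end())
            if um is not None and um.start() - end <= UNIT_ATTACH_WINDOW:
                unit_id = (units or UnitTable([])).lookup(um.group(0))
                span_end = um.end()
        if unit_id is None and after[:1].isalnum():
            continue  # number embedded in a longer alphanumeric token
        num = _parse_number(m.group(0))
        points.append(
            ValueMention(
                make_span(text, start, span_end),
                ValueMentionKind.QUANT,
                num,
                num,
                m.group(0),
                m.group(0),
                unit_id=unit_id,
            )
        )
    return merge_ranges(points, text)


def find_qualitative_values(text: str, qual: QualLexicon) -> list[ValueMention]:
    """Boundary-respecting qualitative grade mentions, merged into ranges."""
    surfaces = sorted(qual.surfaces(), key=len, reverse=True)
    if not surfaces:
        return []
    body = "|".join(r"\s+".join(re.escape(t) for t in s.split()) for s in surfaces)
    pat = re.compile(rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", re.IGNORECASE)
    points = []
    for m in pat.finditer(text):
        rank = qual.rank_of(m.group(0))
        if rank is None:  # pragma: no cover
            continue
        points.append(
            ValueMention(
                make_span(text, m.start(), m.end()),
                ValueMentionKind.QUAL,
                rank,
                rank,
                m.group(0),
                m.group(0),
            )
        )
    return merge_ranges(points, text)


def find_units(text: str, units: UnitTable, exclude: Sequence[ValueMention] = ()) -> list[UnitMention]:
    """Unit mentions not already consumed inside a value mention."""
    unit_re = _compile_unit_alternation(units)
    if unit_re is None:
        return []
    out = []
    for m in unit_re.finditer(text):
        span = make_span(text, m.start(), m.end())
        if any(span.overlaps(v.span) for v in exclude):
            continue
        uid = units.lookup(m.group(0))
        if uid is not None:
            out.append(UnitMention(span, uid))
    return out


def merge_ranges(values: Sequence[ValueMention], text: str) -> list[ValueMention]:
    """Left-greedy merge of adjacent same-kind point values into ranges.

    Only two *point* mentions merge, so a chain "40 - 45 - 50" yields the
    range 40-45 plus the point 50 deterministically.  The merged unit is the
    right endpoint's when present, else the left's.
    """
    values = sorted(values, key=lambda v: (v.span.start, v.span.end))
    out: list[ValueMention] = []
    i = 0
    while i < len(values):
        a = values[i]
        if i + 1 < len(values):
            b = values[i + 1]
            gap = text[a.span.end : b.span.start]
            if (
                not a.is_range
                and not b.is_range
                and a.kind == b.kind
                and a.span.end <= b.span.start
                and RANGE_CONNECTOR_RE.fullmatch(gap)
            ):
                lo, hi = sorted((a.low, b.low))
                out.append(
                    ValueMention(
                        make_span(text, a.span.start, b.span.end),
                        a.kind,
                        lo,
                        hi,
                        a.low_text,
                        b.high_text,
                        unit_id=b.unit_id if b.unit_id is not None else a.unit_id,
                        is_range=True,
                    )
                )
                i += 2
                continue
        out.append(a)
        i += 1
    return out
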