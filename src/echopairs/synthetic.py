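"""Synthetic echocardiogram-style reports with exact gold annotations.

Real echocardiogram text comes in three shapes: semi-structured measurement
blocks (one ``TERM = value unit`` statement per line), narrative prose
("The ejection fraction was visually estimated in a range of 50 to 55%"),
and mixed reports that tabulate a measurement and then restate it in an
interpretation section (a "repeated mention").  The generator emulates
those shapes — with term-variant sampling, optional single-character
misspellings of term words, and distractor lines (demographics, rhythm
statements) — and records a gold annotation for every pair it writes, so
the whole pipeline is testable without clinical data.

Plausible per-concept value ranges are generator metadata only; the
extractor never sees or enforces them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus_tools import Document
from .lexicon import ValueKind, normalize_surface
from .resources import ResourceBundle, load_resources


@dataclass(frozen=True)
class GeneratorProfile:
    seed: int = 0
    n_docs: int = 100
    format_mix: tuple[tuple[str, float], ...] = (
        ("semi_structured", 0.4),
        ("narrative", 0.3),
        ("mixed", 0.3),
    )
    concepts_per_doc: tuple[int, int] = (4, 10)
    variant_noise: float = 0.3
    misspelling_noise: float = 0.0
    distractor_rate: float = 0.3
    repeat_rate: float = 0.5  # chance a mixed doc restates one pair

    def __post_init__(self):
        total = sum(w for _, w in self.format_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"format_mix weights sum to {total}, expected 1")
        for name in ("variant_noise", "misspelling_noise", "distractor_rate", "repeat_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    concept_id: str
    value_low: float
    value_high: float
    value_kind: str  # QUANT | QUAL
    unit_id: str | None
    term_start: int
    term_end: int
    is_repeated: bool = False


# concept_id -> (low, high, decimals, unit_id or None) for quantitative output
_VALUE_SPECS: dict[str, tuple[float, float, int, str | None]] = {
    "left_ventricular_ejection_fraction": (15, 75, 0, "percent"),
    "left_ventricular_dimension_end_diastole": (35, 70, 0, "mm"),
    "left_ventricular_dimension_end_systole": (20, 55, 0, "mm"),
    "left_ventricular_size": (35, 65, 0, "mm"),
    "left_ventricular_posterior_wall_thickness_end_diastole": (6, 15, 0, "mm"),
    "interventricular_septum_dimension_end_diastole": (6, 16, 0, "mm"),
    "left_atrium_size_end_systole": (28, 55, 0, "mm"),
    "e_e_prime_ratio": (4, 20, 0, None),
    "aortic_valve_max_pressure_gradient": (5, 90, 0, "mmhg"),
    "aortic_valve_mean_pressure_gradient": (3, 55, 0, "mmhg"),
    "aortic_valve_orifice_area": (0.6, 4.0, 1, "cm2"),
    "aortic_valve_regurgitation_peak_velocity": (1.0, 5.5, 1, "m_s"),
    "mitral_valve_mean_pressure_gradient": (2, 20, 0, "mmhg"),
    "mitral_valve_orifice_area": (0.8, 6.0, 1, "cm2"),
    "mitral_valve_regurgitation_peak_velocity": (3.0, 6.5, 1, "m_s"),
    "pulmonary_artery_pressure": (15, 80, 0, "mmhg"),
    "right_atrial_pressure": (3, 20, 0, "mmhg"),
    "tricuspid_valve_mean_pressure_gradient": (1, 12, 0, "mmhg"),
    "tricuspid_valve_regurgitation_peak_velocity": (1.5, 4.5, 1, "m_s"),
    "tricuspid_valve_orifice_area": (1.0, 7.0, 1, "cm2"),
}

_UNIT_SURFACE = {"percent": "%", "mm": "mm", "cm": "cm", "cm2": "cm2",
                 "m_s": "m/s", "cm_s": "cm/s", "mmhg": "mmHg"}

_QUAL_POOLS: dict[str, list[str]] = {
    "left_ventricular_ejection_fraction": ["normal", "reduced", "depressed", "preserved", "hyperdynamic"],
    "left_ventricular_contractility": ["normal", "reduced", "depressed", "preserved"],
    "left_ventricular_size": ["normal", "borderline", "mild", "moderate", "severe"],
    "left_atrium_size_end_systole": ["normal", "borderline", "mild", "moderate", "severe"],
    "left_ventricular_hypertrophy": ["mild", "moderate", "severe"],
}
_QUAL_DEFAULT = ["trace", "mild", "moderate", "moderately severe", "severe"]
_QUAL_RANGE_PAIRS = [("trace", "mild"), ("mild", "moderate"), ("moderate", "severe")]

#: concepts the within-term narrative template can express ("the aortic
#: valve has mild stenosis" -> head+tail concatenates to a dictionary surface)
_WITHIN_TEMPLATES = {
    "aortic_valve_stenosis": ("aortic valve", "stenosis"),
    "mitral_valve_stenosis": ("mitral valve", "stenosis"),
    "aortic_valve_regurgitation": ("aortic valve", "regurgitation"),
    "mitral_valve_regurgitation": ("mitral valve", "regurgitation"),
    "tricuspid_valve_regurgitation": ("tricuspid valve", "regurgitation"),
}

_SEMI_DISTRACTORS = [
    "Patient Name: DOE, JOHN",
    "Study Date: 03/14/2012",
    "Referring Provider: Dr. Lee",
    "Heart rate: 72 bpm",
    "Technically limited study.",
    "Normal sinus rhythm.",
    "No pericardial effusion.",
]
_NARRATIVE_DISTRACTORS = [
    "The study quality was adequate.",
    "Normal sinus rhythm.",
    "No pericardial effusion.",
    "Compared with the prior study, there is no significant change.",
]

#: sampling weight per concept (LVEF is always present; the two concepts
#: that real reports mention extremely rarely get a token weight)
_CONCEPT_WEIGHTS = {
    "left_ventricular_dimension_end_diastole": 4,
    "left_ventricular_dimension_end_systole": 3,
    "left_atrium_size_end_systole": 4,
    "interventricular_septum_dimension_end_diastole": 3,
    "left_ventricular_posterior_wall_thickness_end_diastole": 3,
    "left_ventricular_size": 3,
    "left_ventricular_hypertrophy": 2,
    "mitral_valve_regurgitation": 3,
    "tricuspid_valve_regurgitation": 3,
    "aortic_valve_regurgitation": 2,
    "aortic_valve_stenosis": 2,
    "pulmonary_artery_pressure": 2,
    "right_atrial_pressure": 2,
    "aortic_valve_regurgitation_peak_velocity": 0.2,
    "tricuspid_valve_orifice_area": 0.2,
}

_TITLES = {
    "semi_structured": ("ECHOCARDIOGRAM REPORT", "Echo"),
    "narrative": ("CARDIOLOGY CLINIC NOTE", "TIU"),
    "mixed": ("TRANSTHORACIC ECHO STUDY", "Radiology"),
}


def _concept_surfaces(resources: ResourceBundle) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for e in resources.entries:
        table.setdefault(e.concept_id, []).append(e.surface)
    return table


class _ValueDraw:
    def __init__(self, kind, low, high, unit_id, low_text, high_text, rendered):
        self.kind = kind
        self.low = low
        self.high = high
        self.unit_id = unit_id
        self.low_text = low_text
        self.high_text = high_text
        self.rendered = rendered
        self.is_range = low_text != high_text


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}" if decimals else str(int(value))


def _draw_quant(rng: random.Random, concept_id: str) -> _ValueDraw:
    lo, hi, dec, unit_id = _VALUE_SPECS[concept_id]
    step = 10 ** -dec
    a = round(rng.uniform(lo, hi) / step) * step
    a = min(max(a, lo), hi)
    unit_txt = _UNIT_SURFACE[unit_id] if unit_id else ""
    if rng.random() < 0.25:  # range value
        width = round(rng.uniform(step, (hi - lo) * 0.15) / step) * step
        b = min(a + max(width, step), hi)
        if b <= a:
            a, b = max(lo, a - step), a
        ta, tb = _fmt(a, dec), _fmt(b, dec)
        joiner = rng.choice(["-", " to ", " - "])
        return _ValueDraw("QUANT", float(ta), float(tb), unit_id, ta, tb, f"{ta}{joiner}{tb}{unit_txt}")
    ta = _fmt(a, dec)
    return _ValueDraw("QUANT", float(ta), float(ta), unit_id, ta, ta, f"{ta}{unit_txt}")


def _draw_qual(rng: random.Random, concept_id: str, resources: ResourceBundle) -> _ValueDraw:
    if rng.random() < 0.2:
        g1, g2 = rng.choice(_QUAL_RANGE_PAIRS)
        r1, r2 = resources.qualitative.rank_of(g1), resources.qualitative.rank_of(g2)
        return _ValueDraw("QUAL", r1, r2, None, g1, g2, f"{g1} to {g2}")
    g = rng.choice(_QUAL_POOLS.get(concept_id, _QUAL_DEFAULT))
    r = resources.qualitative.rank_of(g)
    return _ValueDraw("QUAL", r, r, None, g, g, g)


def _misspell(surface: str, char_rng: random.Random) -> str:
    words = surface.split(" ")
    idx = [i for i, w in enumerate(words) if len(w) >= 3 and w.isalpha()]
    if not idx:
        return surface
    wi = char_rng.choice(idx)
    w = words[wi]
    pos = char_rng.randrange(len(w))
    if char_rng.random() < 0.5 and len(w) > 3:
        w = w[:pos] + w[pos + 1 :]
    else:
        repl = char_rng.choice("abcdefghijklmnopqrstuvwxyz")
        w = w[:pos] + repl + w[pos + 1 :]
    words[wi] = w
    return " ".join(words)


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.offset = 0
        self.gold: list[GoldAnnotation] = []

    def add_line(self, line: str, term_offset: int | None = None, term_len: int = 0,
                 annotation: dict | None = None):
        if annotation is not None and term_offset is not None:
            self.gold.append(
                GoldAnnotation(
                    doc_id=self.doc_id,
                    term_start=self.offset + term_offset,
                    term_end=self.offset + term_offset + term_len,
                    **annotation,
                )
            )
        self.parts.append(line)
        self.offset += len(line) + 1

    def text(self) -> str:
        return "\n".join(self.parts)


def _pick_surface(rng, surfaces: Sequence[str], variant_noise: float) -> str:
    if len(surfaces) > 1 and rng.random() < variant_noise:
        return rng.choice(surfaces[1:])
    return surfaces[0]


def generate_report(
    profile: GeneratorProfile, doc_index: int, resources: ResourceBundle | None = None
) -> tuple[Document, list[GoldAnnotation]]:
    """Deterministically generate one report and its gold annotations."""
    resources = resources or _default_resources()
    rng = random.Random(profile.seed * 1_000_003 + doc_index)
    noise_rng = random.Random(profile.seed * 2_000_003 + doc_index + 1)
    surfaces = _concept_surfaces(resources)

    fmt = rng.choices([f for f, _ in profile.format_mix], [w for _, w in profile.format_mix])[0]
    title, source_type = _TITLES[fmt]
    doc_id = f"doc{doc_index:05d}"
    builder = _DocBuilder(doc_id)

    n_concepts = rng.randint(*profile.concepts_per_doc)
    pool = [c.concept_id for c in resources.concepts
            if c.concept_id != "left_ventricular_ejection_fraction"]
    weights = [_CONCEPT_WEIGHTS.get(cid, 1.0) for cid in pool]
    chosen = ["left_ventricular_ejection_fraction"]
    while len(chosen) < n_concepts and pool:
        pick = rng.choices(range(len(pool)), weights)[0]
        chosen.append(pool.pop(pick))
        weights.pop(pick)

    def term_text(concept_id: str, upper: bool) -> str:
        s = _pick_surface(rng, surfaces[concept_id], profile.variant_noise)
        u = noise_rng.random()
        if u < profile.misspelling_noise:
            s = _misspell(s, random.Random(int(u * 2**30) * 31 + doc_index))
        return s.upper() if upper else s

    def draw_value(concept_id: str) -> _ValueDraw:
        concept = resources.concept_map[concept_id]
        if concept.value_kind is ValueKind.QUANTITATIVE:
            return _draw_quant(rng, concept_id)
        if concept.value_kind is ValueKind.QUALITATIVE:
            return _draw_qual(rng, concept_id, resources)
        if rng.random() < 0.7 and concept_id in _VALUE_SPECS:
            return _draw_quant(rng, concept_id)
        return _draw_qual(rng, concept_id, resources)

    def annotation(concept_id, v: _ValueDraw, repeated=False) -> dict:
        return {
            "concept_id": concept_id,
            "value_low": float(v.low),
            "value_high": float(v.high),
            "value_kind": v.kind,
            "unit_id": v.unit_id,
            "is_repeated": repeated,
        }

    def semi_line(concept_id, v: _ValueDraw, repeated=False):
        surf = term_text(concept_id, upper=True)
        sep = rng.choice([" = ", ": ", " : "])
        line = f"{surf}{sep}{v.rendered}"
        builder.add_line(line, 0, len(surf), annotation(concept_id, v, repeated))

    def narrative_sentence(concept_id, v: _ValueDraw, repeated=False):
        surf = term_text(concept_id, upper=False)
        ann = annotation(concept_id, v, repeated)
        if v.kind == "QUAL" and not v.is_range and rng.random() < 0.4:
            if concept_id in _WITHIN_TEMPLATES and rng.random() < 0.5:
                head, tail = _WITHIN_TEMPLATES[concept_id]
                line = f"The {head} has {v.rendered} {tail}."
                builder.add_line(line, 4, len(f"{head} has {v.rendered} {tail}"), ann)
            else:
                lead = rng.choice(["There is ", "There is evidence of "])
                line = f"{lead}{v.rendered} {surf}."
                builder.add_line(line, len(lead) + len(v.rendered) + 1, len(surf), ann)
            return
        verb = rng.choice(["was", "is"])
        if v.kind == "QUANT" and v.is_range and rng.random() < 0.5:
            line = f"The {surf} {verb} visually estimated in a range of {v.rendered}."
        elif v.kind == "QUANT" and rng.random() < 0.3:
            line = f"The {surf} {verb} measured at {v.rendered}."
        else:
            line = f"The {surf} {verb} {v.rendered}."
        builder.add_line(line, 4, len(surf), ann)

    def add_distractor(pool_lines):
        if rng.random() < profile.distractor_rate:
            builder.add_line(rng.choice(pool_lines))

    drawn = [(cid, draw_value(cid)) for cid in chosen]

    if fmt in ("semi_structured", "mixed"):
        builder.add_line(title)
        add_distractor(_SEMI_DISTRACTORS)
        semi_part = drawn if fmt == "semi_structured" else drawn[: max(1, len(drawn) // 2)]
        for cid, v in semi_part:
            semi_line(cid, v)
            add_distractor(_SEMI_DISTRACTORS)
        rest = [] if fmt == "semi_structured" else drawn[max(1, len(drawn) // 2) :]
    else:
        builder.add_line(title)
        semi_part, rest = [], drawn

    if rest or fmt == "mixed":
        builder.add_line("IMPRESSION:")
        for cid, v in rest:
            narrative_sentence(cid, v)
            add_distractor(_NARRATIVE_DISTRACTORS)
        if fmt == "mixed" and semi_part and rng.random() < profile.repeat_rate:
            cid, v = semi_part[rng.randrange(len(semi_part))]
            narrative_sentence(cid, v, repeated=True)

    doc = Document(doc_id, builder.text(), source_type, title)
    return doc, builder.gold


def generate_corpus(
    profile: GeneratorProfile, resources: ResourceBundle | None = None
) -> tuple[list[Document], list[GoldAnnotation]]:
    resources = resources or _default_resources()
    docs, gold = [], []
    for i in range(profile.n_docs):
        d, g = generate_report(profile, i, resources)
        docs.append(d)
        gold.extend(g)
    return docs, gold


def gold_to_frame(gold: Sequence[GoldAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "doc_id": g.doc_id,
                "concept_id": g.concept_id,
                "value_low": g.value_low,
                "value_high": g.value_high,
                "value_kind": g.value_kind,
                "unit_id": g.unit_id or "",
                "term_start": g.term_start,
                "term_end": g.term_end,
                "is_repeated": g.is_repeated,
            }
            for g in gold
        ],
        columns=[
            "doc_id", "concept_id", "value_low", "value_high", "value_kind",
            "unit_id", "term_start", "term_end", "is_repeated",
        ],
    )


def write_corpus(
    profile: GeneratorProfile,
    out_dir: str | Path,
    resources: ResourceBundle | None = None,
) -> tuple[Path, Path]:
    from .corpus_tools import write_corpus_jsonl

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs, gold = generate_corpus(profile, resources)
    corpus_path = out / "corpus.jsonl"
    gold_path = out / "gold.csv"
    write_corpus_jsonl(docs, corpus_path)
    gold_to_frame(gold).to_csv(gold_path, index=False)
    return corpus_path, gold_path


_CACHED_RESOURCES: ResourceBundle | None = None


def _default_resources() -> ResourceBundle:
    global _CACHED_RESOURCES
    if _CACHED_RESOURCES is None:
        _CACHED_RESOURCES = load_resources()
    return _CACHED_RESOURCES
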