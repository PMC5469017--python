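"""Corpus filtering, bootstrapping-style term harvesting, and evaluation.

The corpus interchange format is JSONL (one document per line with doc_id,
source_type, title, text) with an equivalent CSV reader.  The harvester
mirrors how the dictionary was originally grown: any line shaped like
``<candidate> = <number><unit>`` whose concept slot is not yet a known
dictionary surface becomes a curation candidate, ranked by frequency.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .concept_mapping import MappingStatus, map_term
from .lexicon import normalize_surface
from .relation_linking import MeasurementValuePair, extract_document
from .term_recognition import (
    build_candidate_terms,
    find_category_words,
    find_phrase_terms,
    resolve_overlaps,
)

SOURCE_TYPES = ("TIU", "Echo", "Radiology", "plain")


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    source_type: str = "plain"
    title: str = ""


class CorpusError(ValueError):
    pass


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    docs, seen = [], set()
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        rec = json.loads(raw)
        doc_id = str(rec["doc_id"])
        if doc_id in seen:
            raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        docs.append(
            Document(doc_id, rec["text"], rec.get("source_type", "plain"), rec.get("title", ""))
        )
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "source_type": d.source_type,
                        "title": d.title,
                        "text": d.text,
                    }
                )
                + "\n"
            )


def read_corpus_csv(path: str | Path) -> list[Document]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    docs = []
    for rec in frame.to_dict("records"):
        docs.append(
            Document(
                str(rec["doc_id"]),
                rec["text"],
                rec.get("source_type", "plain") or "plain",
                rec.get("title", ""),
            )
        )
    if len({d.doc_id for d in docs}) != len(docs):
        raise CorpusError(f"{path}: duplicate doc_id")
    return docs


# ---------------------------------------------------------------------------
# corpus filters


def filter_corpus_by_title(
    corpus: Sequence[Document], substrings: Sequence[str] = ("echo", "card")
) -> list[Document]:
    """Keep documents whose lower-cased title contains any of *substrings*."""
    subs = [s.lower() for s in substrings]
    return [d for d in corpus if any(s in d.title.lower() for s in subs)]


def count_mapped_mentions(doc: Document, resources) -> int:
    """Mapped target-concept mentions in one document (mapping stage only)."""
    text = doc.text
    phrase = find_phrase_terms(text, resources.entries, resources.abbreviation_patterns)
    words = find_category_words(text, resources.lexicon)
    mentions = resolve_overlaps(list(phrase) + list(build_candidate_terms(words, text)))
    n = 0
    for m in mentions:
        result = map_term(
            m, resources.entries, resources.concept_map, resources.lexicon, resources.constraints
        )
        if result.status is MappingStatus.MAPPED:
            n += 1
    return n


def filter_docs_by_concept_count(
    corpus: Sequence[Document], resources, min_count: int = 10
) -> list[Document]:
    """Keep documents with at least *min_count* mapped concept mentions,
    a surrogate for 'this really is an echocardiogram report'."""
    return [d for d in corpus if count_mapped_mentions(d, resources) >= min_count]


# ---------------------------------------------------------------------------
# semantic-bootstrapping harvest


@dataclass
class CandidateTerm:
    surface: str
    frequency: int
    sample_contexts: list[str] = field(default_factory=list)


_HARVEST_LINE = re.compile(
    r"^\s*(?P<cand>[A-Za-z][A-Za-z' /\-]{1,60}?)\s*[=:]\s*"
    r"(?P<num>\d+(?:\.\d+)?(?:\s*(?:-|to)\s*\d+(?:\.\d+)?)?)\s*"
    r"(?P<unit>[%A-Za-z/^2 ]{0,12})\s*$"
)


def harvest_term_candidates(
    corpus: Sequence[Document], resources, max_contexts: int = 3
) -> list[CandidateTerm]:
    """Collect unknown strings occupying the concept slot of a value line.

    Only lines shaped ``<candidate><= or :><number><optional unit>`` are
    mined; candidates already in the dictionary are skipped.  Output is
    sorted by descending frequency for human curation.
    """
    known = {e.surface for e in resources.entries}
    found: dict[str, CandidateTerm] = {}
    for doc in corpus:
        for line in doc.text.split("\n"):
            m = _HARVEST_LINE.match(line)
            if m is None:
                continue
            cand = normalize_surface(m.group("cand"))
            if not cand or cand in known:
                continue
            ct = found.setdefault(cand, CandidateTerm(cand, 0))
            ct.frequency += 1
            if len(ct.sample_contexts) < max_contexts:
                ct.sample_contexts.append(line.strip())
    return sorted(found.values(), key=lambda c: (-c.frequency, c.surface))


def write_candidates_csv(candidates: Sequence[CandidateTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["candidate", "frequency", "decision", "contexts"])
        for c in candidates:
            writer.writerow([c.surface, c.frequency, "", " | ".join(c.sample_contexts)])


def merge_accepted_candidates(candidates_path: str | Path, dictionary_path: str | Path) -> int:
    """Append curated candidates (decision column = a concept_id) to the
    dictionary file; returns how many entries were added."""
    frame = pd.read_csv(candidates_path, dtype=str, keep_default_na=False)
    added = 0
    with open(dictionary_path, "a", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        for rec in frame.to_dict("records"):
            decision = rec.get("decision", "").strip()
            if decision:
                writer.writerow([normalize_surface(rec["candidate"]), decision])
                added += 1
    return added


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class Metrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    fn_collapsed: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def recall_collapsed(self) -> float:
        return self.tp / (self.tp + self.fn_collapsed) if self.tp + self.fn_collapsed else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalResult:
    overall: Metrics
    per_concept: dict[str, Metrics]
    collapse_repeated: bool = False


def _value_key(low, high) -> tuple:
    return (float(low), float(high))


def _pair_key(doc_id, concept_id, low, high) -> tuple:
    return (doc_id, concept_id) + _value_key(low, high)


def evaluate(
    predicted: Sequence[MeasurementValuePair | dict],
    gold: Sequence[dict],
    collapse_repeated: bool = False,
) -> EvalResult:
    """Pair-level scoring against gold annotations.

    A prediction is a true positive when concept, both value endpoints and
    (if the gold record names one) the unit match a not-yet-claimed gold
    annotation of the same document.  With *collapse_repeated*, a missed
    gold annotation whose (concept, value) was correctly extracted elsewhere
    in the same document does not count against recall.
    """
    preds = [_as_pred_record(p) for p in predicted]
    golds = [_as_gold_record(g) for g in gold]
    pred_docs = {p["doc_id"] for p in preds}
    gold_docs = {g["doc_id"] for g in golds}
    if pred_docs - gold_docs:
        raise CorpusError(
            f"predictions reference documents absent from gold: {sorted(pred_docs - gold_docs)[:5]}"
        )

    per_concept: dict[str, Metrics] = {}
    matched_gold: set[int] = set()
    tp_keys: set[tuple] = set()

    for p in preds:
        hit = None
        for gi, g in enumerate(golds):
            if gi in matched_gold:
                continue
            if g["doc_id"] != p["doc_id"] or g["concept_id"] != p["concept_id"]:
                continue
            if _value_key(g["low"], g["high"]) != _value_key(p["low"], p["high"]):
                continue
            if g["unit_id"] is not None and g["unit_id"] != p["unit_id"]:
                continue
            hit = gi
            break
        m = per_concept.setdefault(p["concept_id"], Metrics())
        if hit is not None:
            matched_gold.add(hit)
            m.tp += 1
            tp_keys.add(_pair_key(p["doc_id"], p["concept_id"], p["low"], p["high"]))
        else:
            m.fp += 1

    for gi, g in enumerate(golds):
        if gi in matched_gold:
            continue
        m = per_concept.setdefault(g["concept_id"], Metrics())
        m.fn += 1
        if _pair_key(g["doc_id"], g["concept_id"], g["low"], g["high"]) not in tp_keys:
            m.fn_collapsed += 1

    overall = Metrics(
        tp=sum(m.tp for m in per_concept.values()),
        fp=sum(m.fp for m in per_concept.values()),
        fn=sum(m.fn for m in per_concept.values()),
        fn_collapsed=sum(m.fn_collapsed for m in per_concept.values()),
    )
    return EvalResult(overall, per_concept, collapse_repeated)


def _as_pred_record(p) -> dict:
    if isinstance(p, MeasurementValuePair):
        return {
            "doc_id": p.doc_id,
            "concept_id": p.concept_id,
            "low": p.value.low,
            "high": p.value.high,
            "unit_id": p.unit_id,
        }
    return {
        "doc_id": str(p["doc_id"]),
        "concept_id": p["concept_id"],
        "low": p["low"] if "low" in p else p["value_low"],
        "high": p["high"] if "high" in p else p["value_high"],
        "unit_id": p.get("unit_id") or p.get("unit") or None,
    }


def _as_gold_record(g) -> dict:
    if not isinstance(g, dict):  # GoldAnnotation dataclass
        return {
            "doc_id": g.doc_id,
            "concept_id": g.concept_id,
            "low": g.value_low,
            "high": g.value_high,
            "unit_id": g.unit_id,
        }
    return {
        "doc_id": str(g["doc_id"]),
        "concept_id": g["concept_id"],
        "low": g["low"] if "low" in g else g["value_low"],
        "high": g["high"] if "high" in g else g["value_high"],
        "unit_id": g.get("unit_id") or g.get("unit") or None,
    }


def eval_report_frame(result: EvalResult) -> pd.DataFrame:
    """Per-concept rows plus an overall row, in a table-shaped report."""
    rows = []
    for cid in sorted(result.per_concept):
        m = result.per_concept[cid]
        rows.append(
            {
                "concept": cid,
                "mentions": m.tp + m.fp,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "precision": round(m.precision, 3),
                "recall": round(m.recall, 3),
                "recall_collapsed": round(m.recall_collapsed, 3),
                "f1": round(m.f1, 3),
            }
        )
    m = result.overall
    rows.append(
        {
            "concept": "OVERALL",
            "mentions": m.tp + m.fp,
            "tp": m.tp,
            "fp": m.fp,
            "fn": m.fn,
            "precision": round(m.precision, 3),
            "recall": round(m.recall, 3),
            "recall_collapsed": round(m.recall_collapsed, 3),
            "f1": round(m.f1, 3),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# corpus-level extraction helpers


def extract_corpus(corpus: Sequence[Document], resources, **kwargs) -> list[MeasurementValuePair]:
    pairs = []
    for doc in corpus:
        pairs.extend(extract_document(doc, resources, **kwargs))
    return pairs


def pairs_to_frame(pairs: Sequence[MeasurementValuePair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "doc_id": p.doc_id,
                "line": p.line_number,
                "concept_id": p.concept_id,
                "value_low": p.value.low,
                "value_high": p.value.high,
                "value_kind": p.value.kind.value,
                "unit": p.unit_id or "",
                "rule_id": p.rule_id,
                "term_text": p.term_span.text,
                "term_start": p.term_span.start,
                "term_end": p.term_span.end,
                "unit_compatible": "" if p.unit_compatible is None else p.unit_compatible,
            }
        )
    columns = [
        "doc_id", "line", "concept_id", "value_low", "value_high", "value_kind",
        "unit", "rule_id", "term_text", "term_start", "term_end", "unit_compatible",
    ]
    return pd.DataFrame(rows, columns=columns)
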