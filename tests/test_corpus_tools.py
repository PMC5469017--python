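"""Corpus filters, the bootstrapping harvester, and the evaluation harness."""

import pytest

from echopairs.corpus_tools import (
    CorpusError,
    Document,
    evaluate,
    eval_report_frame,
    extract_corpus,
    filter_corpus_by_title,
    filter_docs_by_concept_count,
    harvest_term_candidates,
    read_corpus_jsonl,
    write_corpus_jsonl,
)
from echopairs.synthetic import GeneratorProfile, generate_report


def _doc(doc_id, text, title=""):
    return Document(doc_id, text, "plain", title)


class TestTitleFilter:
    def test_echo_title_retained(self):
        docs = [
            _doc("a", "", "ECHOCARDIOGRAM REPORT"),
            _doc("b", "", "PODIATRY NOTE"),
            _doc("c", "", ""),
            _doc("d", "", "Cardiology consult"),
        ]
        kept = filter_corpus_by_title(docs)
        assert [d.doc_id for d in kept] == ["a", "d"]


class TestConceptCountFilter:
    def test_synthetic_report_passes_threshold(self, resources):
        profile = GeneratorProfile(seed=11, n_docs=1, concepts_per_doc=(12, 12))
        doc, gold = generate_report(profile, 0, resources)
        assert len(gold) >= 12
        assert filter_docs_by_concept_count([doc], resources, 10) == [doc]

    def test_empty_document_removed(self, resources):
        doc = _doc("x", "no cardiac content here")
        assert filter_docs_by_concept_count([doc], resources, 10) == []

    def test_zero_threshold_keeps_all(self, resources):
        docs = [_doc("x", "nothing"), _doc("y", "LVEF = 55%")]
        assert filter_docs_by_concept_count(docs, resources, 0) == docs


class TestHarvest:
    def test_unknown_value_line_candidate(self, resources):
        docs = [_doc(f"d{i}", "LV EJ FRACT: 55%\nfiller") for i in range(5)]
        cands = harvest_term_candidates(docs, resources)
        assert [(c.surface, c.frequency) for c in cands] == [("lv ej fract", 5)]
        assert len(cands[0].sample_contexts) <= 3

    def test_pure_narrative_yields_nothing(self, resources):
        docs = [_doc("d", "The patient reports feeling well since the last visit.")]
        assert harvest_term_candidates(docs, resources) == []

    def test_known_surface_not_emitted(self, resources):
        docs = [_doc("d", "LVEF: 55%")]
        assert harvest_term_candidates(docs, resources) == []

    def test_frequencies_sum_to_matching_lines(self, resources):
        docs = [
            _doc("a", "AO ROOT = 31mm\nAO ROOT = 33mm"),
            _doc("b", "AO ROOT: 35 mm\nPEAK VEL THING: 2.1 m/s"),
        ]
        cands = harvest_term_candidates(docs, resources)
        assert sum(c.frequency for c in cands) == 4


class TestEvaluate:
    GOLD2 = [
        {"doc_id": "d", "concept_id": "lvef", "low": 55, "high": 55, "unit_id": "percent"},
        {"doc_id": "d", "concept_id": "mr", "low": 2, "high": 2, "unit_id": None},
    ]

    def test_perfect_predictions(self):
        preds = [dict(g) for g in self.GOLD2]
        m = evaluate(preds, self.GOLD2).overall
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_degenerate_zero_counts(self):
        m = evaluate([], []).overall
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_repeated_mention_collapsed_recall(self):
        gold = [
            {"doc_id": "d", "concept_id": "lvef", "low": 55, "high": 55, "unit_id": "percent"},
            {"doc_id": "d", "concept_id": "lvef", "low": 55, "high": 55, "unit_id": "percent"},
        ]
        preds = [dict(gold[0])]
        res = evaluate(preds, gold)
        assert res.overall.recall == pytest.approx(0.5)
        assert res.overall.recall_collapsed == pytest.approx(1.0)

    def test_unit_checked_only_when_gold_specifies(self):
        gold = [{"doc_id": "d", "concept_id": "lvef", "low": 55, "high": 55, "unit_id": None}]
        preds = [{"doc_id": "d", "concept_id": "lvef", "low": 55, "high": 55, "unit_id": "percent"}]
        assert evaluate(preds, gold).overall.tp == 1
        gold2 = [{"doc_id": "d", "concept_id": "lvef", "low": 55, "high": 55, "unit_id": "mm"}]
        assert evaluate(preds, gold2).overall.tp == 0

    def test_doc_id_mismatch_raises(self):
        preds = [{"doc_id": "other", "concept_id": "lvef", "low": 1, "high": 1, "unit_id": None}]
        with pytest.raises(CorpusError):
            evaluate(preds, self.GOLD2)

    def test_document_order_invariance_and_sum_consistency(self, resources):
        profile = GeneratorProfile(seed=5, n_docs=10, misspelling_noise=0.2)
        docs, gold = [], []
        for i in range(profile.n_docs):
            d, g = generate_report(profile, i, resources)
            docs.append(d)
            gold.extend(g)
        pairs = extract_corpus(docs, resources)
        fwd = evaluate(pairs, gold)
        rev = evaluate(list(reversed(pairs)), list(reversed(gold)))
        assert (fwd.overall.tp, fwd.overall.fp, fwd.overall.fn) == (
            rev.overall.tp, rev.overall.fp, rev.overall.fn,
        )
        assert fwd.overall.tp == sum(m.tp for m in fwd.per_concept.values())
        assert fwd.overall.fn == sum(m.fn for m in fwd.per_concept.values())
        assert fwd.overall.recall_collapsed >= fwd.overall.recall

    def test_report_frame_has_overall_row(self):
        frame = eval_report_frame(evaluate([dict(g) for g in self.GOLD2], self.GOLD2))
        assert list(frame["concept"])[-1] == "OVERALL"
        assert set(["precision", "recall", "recall_collapsed", "f1"]) <= set(frame.columns)


def test_curation_round_trip_appends_accepted_candidates(tmp_path, resources):
    """Accepted harvest candidates merge back into a dictionary file."""
    import csv

    from echopairs.corpus_tools import merge_accepted_candidates, write_candidates_csv
    from echopairs.lexicon import dump_dictionary, load_dictionary

    docs = [_doc("d", "AO ROOT = 31mm\nSOMETHING ELSE: 2")]
    cands = harvest_term_candidates(docs, resources)
    cand_path = tmp_path / "candidates.csv"
    write_candidates_csv(cands, cand_path)

    rows = list(csv.DictReader(cand_path.open()))
    for row in rows:
        row["decision"] = "aortic_valve_orifice_area" if row["candidate"] == "ao root" else ""
    with cand_path.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=rows[0].keys())
        w.writeheader()
        w.writerows(rows)

    dict_path = tmp_path / "dictionary.csv"
    dump_dictionary(resources.entries, dict_path)
    added = merge_accepted_candidates(cand_path, dict_path)
    assert added == 1
    entries, _ = load_dictionary(dict_path, resources.concepts)
    assert any(e.surface == "ao root" for e in entries)


def test_corpus_jsonl_round_trip(tmp_path):
    docs = [
        Document("a", "LVEF = 55%\n", "Echo", "ECHO REPORT"),
        Document("b", "plain text", "TIU", ""),
    ]
    path = tmp_path / "corpus.jsonl"
    write_corpus_jsonl(docs, path)
    assert read_corpus_jsonl(path) == docs


def test_corpus_duplicate_doc_id_rejected(tmp_path):
    path = tmp_path / "corpus.jsonl"
    path.write_text('{"doc_id": "a", "text": "x"}\n{"doc_id": "a", "text": "y"}\n')
    with pytest.raises(CorpusError, match="duplicate"):
        read_corpus_jsonl(path)
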