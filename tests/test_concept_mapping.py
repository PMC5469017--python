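"""Two-step lookup: exact match, token-overlap scoring, constraint
disambiguation, and agreement with a brute-force oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echopairs.concept_mapping import (
    STOP_TOKENS,
    MappingStatus,
    apply_semantic_constraints,
    exact_match,
    map_term,
    token_overlap_scores,
)
from echopairs.lexicon import (
    Concept,
    ConstraintSet,
    TermEntry,
    ValueKind,
    WordCategory,
    WordEntry,
    WordLexicon,
)

C_LVDD = "left_ventricular_dimension_end_diastole"
C_LA = "left_atrium_size_end_systole"

TWO_ENTRY_DICT = [
    TermEntry("left ventricular dimension at end diastole", C_LVDD),
    TermEntry("left atrium diameter", C_LA),
]


def brute_force_scores(surface: str, entries) -> dict[str, int]:
    """Independent nested-loop scorer: for every (query token, entry) pair,
    count distinct query tokens appearing in any surface of each concept."""
    from echopairs.lexicon import normalize_surface

    query = []
    for tok in normalize_surface(surface).split():
        if tok not in STOP_TOKENS and tok not in query:
            query.append(tok)
    matched: dict[str, set[str]] = {}
    for tok in query:
        for e in entries:
            if tok in e.surface.split():
                matched.setdefault(e.concept_id, set()).add(tok)
    return {cid: len(toks) for cid, toks in matched.items()}


def test_exact_match_identity_and_miss():
    entries = [TermEntry("lvef", "left_ventricular_ejection_fraction")]
    assert exact_match("lvef", entries) == "left_ventricular_ejection_fraction"
    assert exact_match("LVEF", entries) == "left_ventricular_ejection_fraction"
    assert exact_match("left ventricular diastolic dimension", entries) is None
    assert exact_match("", entries) is None


def test_token_overlap_worked_example():
    scores = dict(token_overlap_scores("left ventricular diastolic dimension", TWO_ENTRY_DICT))
    assert scores == {C_LVDD: 3, C_LA: 1}


def test_token_overlap_self_match_upper_bound():
    surface = "left ventricular dimension at end diastole"
    scores = dict(token_overlap_scores(surface, TWO_ENTRY_DICT))
    # stop tokens ("at") do not score
    content = [t for t in surface.split() if t not in STOP_TOKENS]
    assert scores[C_LVDD] == len(content)


def test_token_overlap_repeated_token_counts_once():
    entries = [TermEntry("mitral valve area", "mitral_valve_orifice_area")]
    scores = dict(token_overlap_scores("area area area", entries))
    assert scores == {"mitral_valve_orifice_area": 1}


def test_token_overlap_matches_bruteforce_on_random_dictionaries():
    """Scorer == independent oracle across 1000 random small dictionaries."""
    rng = random.Random(20240917)
    vocab = ["left", "right", "atrium", "ventricular", "dimension", "area",
             "volume", "peak", "mean", "of", "the", "at", "velocity", "e"]
    for _ in range(1000):
        entries = [
            TermEntry(
                " ".join(rng.choices(vocab, k=rng.randint(1, 4))),
                f"C{rng.randint(0, 4)}",
            )
            for _ in range(rng.randint(1, 6))
        ]
        query = " ".join(rng.choices(vocab, k=rng.randint(1, 5)))
        assert dict(token_overlap_scores(query, entries)) == brute_force_scores(query, entries)


def _mini_semantics():
    lexicon = WordLexicon(
        [
            WordEntry("atrial", WordCategory.ANATOMY, "atrium"),
            WordEntry("ventricular", WordCategory.ANATOMY, "ventricle"),
            WordEntry("volume", WordCategory.MEASURE, "volume"),
            WordEntry("dimension", WordCategory.MEASURE, "dimension"),
        ]
    )
    constraints = ConstraintSet(
        [("atrium", "ventricle"), ("atrium", "mitral"), ("atrium", "tricuspid"),
         ("volume", "dimension"), ("volume", "velocity"), ("volume", "pressure")]
    )
    concepts = {
        "lv_dim": Concept("lv_dim", "LV dimension", ValueKind.QUANTITATIVE,
                          anatomy_tags=frozenset({"left", "ventricle"}),
                          measure_tags=frozenset({"dimension"})),
        "mv_regurg": Concept("mv_regurg", "MR", ValueKind.QUALITATIVE,
                             anatomy_tags=frozenset({"mitral"}),
                             measure_tags=frozenset({"regurgitation"})),
        "la_size": Concept("la_size", "LA size", ValueKind.BOTH,
                           anatomy_tags=frozenset({"left", "atrium"}),
                           measure_tags=frozenset({"size"})),
    }
    return lexicon, constraints, concepts


def test_constraints_discard_excluded_anatomy():
    """'atrial' in the phrase discards ventricular and mitral concepts."""
    lexicon, constraints, concepts = _mini_semantics()
    scored = [("lv_dim", 2), ("mv_regurg", 2), ("la_size", 2)]
    kept = apply_semantic_constraints("left atrial dimension", scored, lexicon, constraints, concepts)
    assert kept == [("la_size", 2)]


def test_constraints_discard_excluded_measures():
    lexicon, constraints, concepts = _mini_semantics()
    kept = apply_semantic_constraints(
        "atrial volume", [("lv_dim", 1), ("la_size", 1)], lexicon, constraints, concepts
    )
    assert kept == [("la_size", 1)]


def test_constraints_noop_without_lexicon_words():
    lexicon, constraints, concepts = _mini_semantics()
    scored = [("lv_dim", 3), ("la_size", 1)]
    assert apply_semantic_constraints("xyz abc", scored, lexicon, constraints, concepts) == scored


@settings(max_examples=200, derandomize=True)
@given(
    scores=st.lists(
        st.tuples(st.sampled_from(["lv_dim", "mv_regurg", "la_size"]), st.integers(1, 5)),
        max_size=6,
    ),
    surface=st.lists(
        st.sampled_from(["atrial", "ventricular", "volume", "dimension", "foo"]),
        min_size=0,
        max_size=4,
    ).map(" ".join),
)
def test_constraint_filter_is_monotone(scores, surface):
    """Filtering never adds candidates and never alters surviving scores."""
    lexicon, constraints, concepts = _mini_semantics()
    kept = apply_semantic_constraints(surface, scores, lexicon, constraints, concepts)
    assert len(kept) <= len(scores)
    remaining = list(scores)
    for item in kept:
        assert item in remaining
        remaining.remove(item)


def test_map_term_prefers_higher_score(resources):
    result = map_term(
        "left ventricular diastolic dimension",
        TWO_ENTRY_DICT,
        resources.concept_map,
        resources.lexicon,
        resources.constraints,
    )
    assert result.status is MappingStatus.MAPPED
    assert result.concept_id == C_LVDD


def test_map_term_unmapped_when_no_token_matches(resources):
    result = map_term(
        "no overlap here", TWO_ENTRY_DICT, resources.concept_map,
        resources.lexicon, resources.constraints,
    )
    assert result.status is MappingStatus.UNMAPPED


def test_map_term_tie_is_ambiguous(resources):
    entries = [
        TermEntry("alpha beta", "aortic_valve_orifice_area"),
        TermEntry("alpha gamma", "mitral_valve_orifice_area"),
    ]
    result = map_term(
        "alpha", entries, resources.concept_map, resources.lexicon, resources.constraints
    )
    assert result.status is MappingStatus.AMBIGUOUS
    assert result.concept_id is None


def test_exact_match_wins_unless_constraints_exclude(resources):
    # exact surface maps...
    ok = map_term("lvef", resources.entries, resources.concept_map,
                  resources.lexicon, resources.constraints)
    assert ok.status is MappingStatus.MAPPED
    # ...but a constraint-violating exact entry is rejected
    bad_entry = [TermEntry("atrial dimension test volume", C_LVDD)]
    res = map_term("atrial dimension test volume", bad_entry, resources.concept_map,
                   resources.lexicon, resources.constraints)
    assert res.status is MappingStatus.UNMAPPED
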