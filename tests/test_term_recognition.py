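"""Phrase/abbreviation matching, word categorization, the concept builder,
and overlap resolution."""

import itertools

import pytest

from echopairs.lexicon import TermEntry, WordCategory
from echopairs.term_recognition import (
    Span,
    TermMention,
    TermOrigin,
    build_candidate_terms,
    find_category_words,
    find_phrase_terms,
    make_span,
    resolve_overlaps,
)


def test_abbreviation_match_with_span():
    text = "The LVEF = 40%"
    mentions = find_phrase_terms(text, [], ["lvef"])
    assert len(mentions) == 1
    m = mentions[0]
    assert (m.span.start, m.span.end) == (4, 8)
    assert m.normalized_surface == "lvef"
    assert m.origin is TermOrigin.ABBREVIATION


def test_empty_text_yields_nothing(resources):
    assert find_phrase_terms("", resources.entries, resources.abbreviation_patterns) == []


def test_token_boundary_blocks_embedded_surface():
    entries = [TermEntry("ef", "left_ventricular_ejection_fraction")]
    assert find_phrase_terms("relief", entries) == []
    assert len(find_phrase_terms("the EF is", entries)) == 1


def test_phrase_terms_do_not_span_lines(resources):
    # "la" + newline + "size" must not assemble into "la size"
    mentions = find_phrase_terms("la\nsize", resources.entries, [])
    assert all("\n" not in m.span.text for m in mentions)


def test_every_dictionary_surface_found_exactly_once(resources):
    """Concatenating all surfaces one per line finds each exactly once."""
    text = "\n".join(e.surface for e in resources.entries)
    mentions = find_phrase_terms(text, resources.entries, [])
    assert len(mentions) == len(resources.entries)
    found = sorted(m.normalized_surface for m in mentions)
    assert found == sorted(e.surface for e in resources.entries)


def test_find_category_words(resources):
    words = find_category_words("left ventricular diastolic dimension", resources.lexicon)
    got = [(w.span.text, w.category) for w in words]
    assert got == [
        ("left", WordCategory.ANATOMY),
        ("ventricular", WordCategory.ANATOMY),
        ("diastolic", WordCategory.MEASURE),
        ("dimension", WordCategory.MEASURE),
    ]


def test_find_category_words_no_hits(resources):
    assert find_category_words("patient feels fine", resources.lexicon) == []


def test_find_category_words_whole_text_is_one_surface(resources):
    words = find_category_words("ventricular", resources.lexicon)
    assert len(words) == 1
    assert (words[0].span.start, words[0].span.end) == (0, 11)


@pytest.mark.parametrize(
    "text,expected_surface",
    [
        (
            "dimension of the left ventricle at the end of diastole",
            "dimension of the left ventricle at the end of diastole",
        ),
        ("left ventricular diastolic dimension", "left ventricular diastolic dimension"),
    ],
)
def test_concept_builder_merges_connected_words(resources, text, expected_surface):
    words = find_category_words(text, resources.lexicon)
    built = build_candidate_terms(words, text)
    assert len(built) == 1
    assert built[0].origin is TermOrigin.BUILT
    assert built[0].normalized_surface == expected_surface


def test_concept_builder_requires_both_categories(resources):
    text = "pressure"
    built = build_candidate_terms(find_category_words(text, resources.lexicon), text)
    assert built == []
    # anatomy-only runs are not terms either
    text2 = "aortic valve"
    assert build_candidate_terms(find_category_words(text2, resources.lexicon), text2) == []


def test_concept_builder_does_not_cross_line_breaks(resources):
    text = "left ventricular\ndimension"
    built = build_candidate_terms(find_category_words(text, resources.lexicon), text)
    assert built == []


def test_concept_builder_breaks_on_non_connector(resources):
    text = "left ventricle shows a dimension"  # "shows" is not a connector
    built = build_candidate_terms(find_category_words(text, resources.lexicon), text)
    assert built == []


def _mention(text, start, end, origin):
    return TermMention(make_span(text, start, end), text[start:end].lower(), origin)


def test_resolve_overlaps_longest_wins():
    text = "x" * 40
    phrase = _mention(text, 0, 30, TermOrigin.PHRASE)
    built = _mention(text, 0, 20, TermOrigin.BUILT)
    assert resolve_overlaps([built, phrase]) == [phrase]


def test_resolve_overlaps_keeps_disjoint():
    text = "x" * 40
    a = _mention(text, 0, 5, TermOrigin.PHRASE)
    b = _mention(text, 10, 15, TermOrigin.BUILT)
    assert resolve_overlaps([b, a]) == [a, b]


def test_resolve_overlaps_deterministic_across_orderings():
    """Three mutually overlapping equal-length mentions: exactly one
    survivor, identical whatever the input order."""
    text = "abcdefghij"
    ms = [
        _mention(text, 0, 6, TermOrigin.BUILT),
        _mention(text, 2, 8, TermOrigin.BUILT),
        _mention(text, 4, 10, TermOrigin.BUILT),
    ]
    results = {tuple(resolve_overlaps(list(perm))) for perm in itertools.permutations(ms)}
    assert len(results) == 1
    (survivors,) = results
    assert len(survivors) == 1
    assert survivors[0].span.start == 0  # leftmost tie-break


def test_span_validation():
    with pytest.raises(ValueError):
        make_span("abc", 2, 2)
    with pytest.raises(ValueError):
        make_span("abc", 1, 9)
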