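import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidrex.corpus import Document, Mention
from cidrex.preprocess import (
    LocationMarker,
    frequency_bin,
    hyponym_tags,
    location_marker,
    normalize_text,
    relative_positions,
    segment_and_tokenize,
)
from ._oracles import hyponym_scalar


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Hospital For Sick Children", "hospital for sick children"),
        (
            "from January 1, 1986, to March 1, 1996",
            "from january <num>, <num>, to march <num>, <num>",
        ),
        ("α-tocopherol", "-tocopherol"),
        ("  double   spaces\tand\ttabs ", "double spaces and tabs"),
        ("dose of 12mg/24h", "dose of <num>mg/<num>h"),
    ],
)
def test_normalize_text_examples(raw, expected):
    assert normalize_text(raw) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(max_size=80))
def test_normalize_text_is_idempotent(text):
    once = normalize_text(text)
    assert normalize_text(once) == once
    assert not any(ch.isdigit() or ch.isupper() for ch in once)


def _doc(title, abstract, mentions=()):
    return Document("d1", title, abstract, list(mentions))


def test_title_is_sentence_zero_and_abstract_splits():
    doc = _doc("X induces Y.", "A first. B second.")
    sents = segment_and_tokenize(doc)
    assert len(sents) == 3
    assert sents[0].in_title and not sents[1].in_title
    assert [s.index for s in sents] == [0, 1, 2]
    # sentence spans land back on the document
    assert doc.sentences == [s.char_span for s in sents]


def test_protected_abbreviations_do_not_split():
    doc = _doc("T.", "We used i.e. Something here. Final sentence.")
    sents = segment_and_tokenize(doc)
    assert len(sents) == 3  # title + 2, not 3, abstract sentences


def test_word_ending_in_abbreviation_letters_still_splits():
    doc = _doc("T.", "Patients lived in Toronto. We analyzed records.")
    assert len(segment_and_tokenize(doc)) == 3


def test_boundary_inside_mention_is_suppressed():
    title = "T."
    abstract = "Patients took St. John wort daily. Next sentence."
    surface = "St. John wort"
    start = len(title) + 1 + abstract.index(surface)
    mention = Mention(start, start + len(surface), surface, "Chemical", "D1")
    # without the mention, ". John" opens a boundary and the abstract splits in three
    assert len(segment_and_tokenize(_doc(title, abstract))) == 4
    sents = segment_and_tokenize(_doc(title, abstract, [mention]))
    assert len(sents) == 3
    containing = [s for s in sents if s.char_span[0] <= mention.start and mention.end <= s.char_span[1]]
    assert len(containing) == 1


def test_every_mention_maps_to_exactly_one_sentence(small_collection):
    for doc in small_collection.documents[:10]:
        sents = segment_and_tokenize(doc)
        for m in doc.mentions:
            containing = [s for s in sents if s.char_span[0] <= m.start and m.end <= s.char_span[1]]
            assert len(containing) == 1


def test_location_markers_cover_exactly_the_four_values():
    doc = _doc("Title here.", "First one. Middle one. Middle two. Last one.")
    sents = segment_and_tokenize(doc)
    n_abs = len(sents) - 1
    marks = [location_marker(s, n_abs) for s in sents]
    assert marks == [
        LocationMarker.T,
        LocationMarker.A_FST,
        LocationMarker.A_MDL,
        LocationMarker.A_MDL,
        LocationMarker.A_LST,
    ]


def test_single_abstract_sentence_is_marked_first():
    doc = _doc("Title.", "Only sentence.")
    sents = segment_and_tokenize(doc)
    assert location_marker(sents[1], 1) == LocationMarker.A_FST


def test_location_marker_rejects_empty_abstract_state():
    doc = _doc("Title.", "Only sentence.")
    sents = segment_and_tokenize(doc)
    with pytest.raises(ValueError):
        location_marker(sents[1], 0)


@pytest.mark.parametrize(
    "n, anchor, max_dist, expected",
    [
        (3, 0, 30, [0, 1, 2]),
        (3, 2, 30, [-2, -1, 0]),
        (4, 0, 1, [0, 1, 1, 1]),
        (5, 2, 1, [-1, -1, 0, 1, 1]),
    ],
)
def test_relative_positions(n, anchor, max_dist, expected):
    assert relative_positions(n, anchor, max_dist) == expected


def test_relative_positions_rejects_anchor_outside_sentence():
    with pytest.raises(IndexError):
        relative_positions(3, 5)


def test_hyponym_tags_toy_tree():
    tree = {"A": ["C18.452"], "B": ["C18.452.394"]}
    assert hyponym_tags({"A", "B"}, tree) == {"A": 0, "B": 1}


def test_hyponym_tags_disjoint_and_singleton():
    assert hyponym_tags({"A"}, {"A": ["C18"]}) == {"A": 1}
    assert hyponym_tags({"A", "B"}, {"A": ["C01"], "B": ["D02"]}) == {"A": 1, "B": 1}


def test_hyponym_missing_concept_defaults_to_one():
    assert hyponym_tags({"A", "Z"}, {"A": ["C01"]})["Z"] == 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_hyponym_tags_match_pairwise_oracle(data):
    codes = st.lists(
        st.integers(1, 3).flatmap(
            lambda d: st.lists(st.integers(0, 2), min_size=d, max_size=d).map(
                lambda parts: ".".join(f"C{p:02d}" for p in parts)
            )
        ),
        min_size=1,
        max_size=3,
    )
    n = data.draw(st.integers(1, 6))
    tree = {f"D{i}": data.draw(codes) for i in range(n)}
    concepts = set(tree)
    assert hyponym_tags(concepts, tree) == hyponym_scalar(concepts, tree)


@pytest.mark.parametrize("count, expected", [(1, 0), (2, 1), (3, 1), (4, 2), (100, 6), (10_000, 7)])
def test_frequency_bin_log2_with_cap(count, expected):
    assert frequency_bin(count) == expected


def test_frequency_bin_rejects_zero():
    with pytest.raises(ValueError):
        frequency_bin(0)
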