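import itertools

import pytest

from cidrex.align import (
    align_collection,
    align_document,
    bags_to_jsonl,
    build_inter_instances,
    build_intra_bags,
    candidate_pairs,
    exclude_documents,
    inter_to_jsonl,
    label_pair,
)
from cidrex.corpus import Document, KBFact, Mention
from cidrex.examples import (
    CHEMICAL,
    NAUSEA,
    PSEUDOTUMOR,
    tetracycline_document,
    tetracycline_kb,
)
from cidrex.preprocess import segment_and_tokenize


def _doc_from_sentences(doc_id, title, sentences, annotations):
    """Build a document annotating (surface, etype, concept, occurrence#) tuples."""
    abstract = " ".join(sentences)
    text = title + " " + abstract
    mentions = []
    for surface, etype, concept, occurrence in annotations:
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(surface, start + 1)
        mentions.append(Mention(start, start + len(surface), surface, etype, concept))
    return Document(doc_id, title, abstract, mentions)


def test_candidate_pairs_are_the_sorted_id_product():
    doc = _doc_from_sentences(
        "d", "T.", ["Bb and aspirin with gout. Aspirin and fever."],
        [
            ("aspirin", "Chemical", "D2", 0),
            ("Aspirin", "Chemical", "D2", 0),
            ("Bb", "Chemical", "D1", 0),
            ("gout", "Disease", "D9", 0),
            ("fever", "Disease", "D8", 0),
        ],
    )
    pairs = candidate_pairs(doc)
    assert pairs == [("D1", "D8"), ("D1", "D9"), ("D2", "D8"), ("D2", "D9")]


def test_candidate_pairs_empty_without_diseases():
    doc = _doc_from_sentences("d", "T.", ["Aspirin here."], [("Aspirin", "Chemical", "D2", 0)])
    assert candidate_pairs(doc) == []


def test_label_pair_positive_only_for_curated_positive_tag():
    kb = {
        KBFact("D013752", "D011559", "marker/mechanism"),
        KBFact("D013752", "D000001", "therapeutic"),
    }
    assert label_pair(("D013752", "D011559"), kb) == 1
    assert label_pair(("D013752", "D999999"), kb) == 0
    assert label_pair(("D013752", "D000001"), kb) == 0


def test_worked_example_intra_bag_has_three_instances():
    """Two chemical mentions x one disease in sentence one, plus one pair in
    sentence two, must yield a single three-instance bag for the co-occurring
    pair."""
    bags, _ = align_document(tetracycline_document(), tetracycline_kb())
    assert len(bags) == 1
    bag = bags[0]
    assert bag.pair == (CHEMICAL, PSEUDOTUMOR)
    assert len(bag.instances) == 3
    assert bag.label == 1
    assert sorted(i.sentence_index for i in bag.instances) == [1, 1, 2]


def test_worked_example_non_cooccurring_pair_becomes_one_inter_instance():
    _, inter = align_document(tetracycline_document(), tetracycline_kb())
    assert len(inter) == 1
    inst = inter[0]
    assert inst.pair == (CHEMICAL, NAUSEA)
    assert inst.label == 1
    assert inst.dis_surfaces == ["nausea"]
    assert inst.nearest is not None
    # the nearest chemical mention is the tetracycline in the same sentence
    # block as the nausea mention's closest neighbour (sentence two)
    assert inst.nearest[0].start > inst.nearest[1].start - 400


def test_minimal_single_instance_bag():
    kb = {KBFact("D1", "D9", "marker/mechanism")}
    doc = _doc_from_sentences(
        "d", "T.", ["Aspirin causes gout."],
        [("Aspirin", "Chemical", "D1", 0), ("gout", "Disease", "D9", 0)],
    )
    bags = build_intra_bags(doc, kb)
    assert len(bags) == 1 and len(bags[0].instances) == 1 and bags[0].label == 1


def test_instance_position_lists_align_with_tokens():
    doc = tetracycline_document()
    bags, _ = align_document(doc, tetracycline_kb())
    for inst in bags[0].instances:
        assert len(inst.tokens) == len(inst.pos_chem) == len(inst.pos_dis)
        assert 0 in inst.pos_chem and 0 in inst.pos_dis


def test_inter_instances_enumerate_all_non_cooccurring_pairs():
    kb = {KBFact("D1", "D8", "marker/mechanism"), KBFact("D1", "D9", "marker/mechanism")}
    doc = _doc_from_sentences(
        "d", "T.",
        ["Aspirin was given. Later gout appeared. Then fever appeared."],
        [
            ("Aspirin", "Chemical", "D1", 0),
            ("gout", "Disease", "D9", 0),
            ("fever", "Disease", "D8", 0),
        ],
    )
    inter = build_inter_instances(doc, kb)
    assert {(x.pair, x.label) for x in inter} == {(("D1", "D8"), 1), (("D1", "D9"), 1)}


def test_partition_every_candidate_pair_exactly_once(small_collection):
    kb = small_collection.kb_facts
    for doc in small_collection.documents:
        bags, inter = align_document(doc, kb, small_collection.mesh_tree)
        bag_pairs = {b.pair for b in bags}
        inter_pairs = {x.pair for x in inter}
        assert not bag_pairs & inter_pairs
        assert bag_pairs | inter_pairs == set(candidate_pairs(doc))


def _brute_force_instance_counts(doc):
    """Count co-located mention pairs per id pair by quadratic enumeration."""
    sents = segment_and_tokenize(doc)
    counts = {}
    for cm, dm in itertools.product(doc.mentions, doc.mentions):
        if cm.etype != "Chemical" or dm.etype != "Disease":
            continue
        same = any(
            s <= cm.start < e and s <= dm.start < e for s, e in (x.char_span for x in sents)
        )
        if same:
            key = (cm.concept_id, dm.concept_id)
            counts[key] = counts.get(key, 0) + 1
    return counts


def test_bag_instance_counts_match_brute_force_oracle(small_collection):
    for doc in small_collection.documents[:15]:
        bags = build_intra_bags(doc, small_collection.kb_facts)
        got = {b.pair: len(b.instances) for b in bags}
        assert got == _brute_force_instance_counts(doc)


def test_alignment_serialization_is_deterministic(small_collection):
    kb, tree = small_collection.kb_facts, small_collection.mesh_tree
    docs = small_collection.documents[:10]
    a_bags, a_inter = align_collection(docs, kb, tree)
    b_bags, b_inter = align_collection(docs, kb, tree)
    assert bags_to_jsonl(a_bags) == bags_to_jsonl(b_bags)
    assert inter_to_jsonl(a_inter) == inter_to_jsonl(b_inter)


def test_cap_negatives_limits_ratio_and_keeps_positives(small_collection):
    from cidrex.align import cap_negatives

    bags, _ = align_collection(
        small_collection.documents, small_collection.kb_facts, small_collection.mesh_tree
    )
    n_pos = sum(b.label for b in bags)
    capped = cap_negatives(bags, max_ratio=1.0, seed=0)
    assert sum(b.label for b in capped) == n_pos
    assert sum(1 - b.label for b in capped) <= n_pos
    # ratio larger than the data is a no-op
    assert cap_negatives(bags, max_ratio=100.0) == bags


def test_exclude_documents_counts():
    docs = [Document(f"d{i}", "T.", "A body.") for i in range(10)]
    kept = exclude_documents(docs, ["d1", "d5", "d7"])
    assert len(kept) == 7
    assert exclude_documents(docs, []) == docs
    assert len(exclude_documents(docs, ["nope"])) == 10
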