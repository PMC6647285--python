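"""Distant-supervision alignment of knowledge-base facts to annotated documents.

For every document, the candidate pairs are the Cartesian product of its
distinct chemical and disease MeSH ids.  A pair whose two ids co-occur in at
least one sentence becomes an intra-sentence relation bag whose instances are
ALL co-located (chemical mention, disease mention) pairs; a pair that never
co-occurs in a sentence becomes a single inter-sentence instance built from
document-level lexical features.  Both are weakly labeled from the knowledge
base: positive iff the id pair is curated with the Marker/Mechanism tag.  The
two cases partition the candidate pairs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import Document, KBFact, Mention
from .preprocess import (
    DEFAULT_MAX_DIST,
    LocationMarker,
    TokenizedSentence,
    frequency_bin,
    hyponym_tags,
    location_marker,
    normalize_token,
    relative_positions,
    segment_and_tokenize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IntraInstance",
    "RelationBag",
    "InterPairInstance",
    "candidate_pairs",
    "label_pair",
    "build_intra_bags",
    "build_inter_instances",
    "align_document",
    "align_collection",
    "exclude_documents",
    "cap_negatives",
    "bags_to_jsonl",
    "inter_to_jsonl",
]


@dataclass
class IntraInstance:
    """One co-located mention pair inside one sentence."""

    sentence_index: int
    chem_mention: Mention
    dis_mention: Mention
    tokens: list[str]  # normalized token strings
    pos_chem: list[int]
    pos_dis: list[int]
    location: LocationMarker

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.pos_chem) == len(self.pos_dis)):
            raise ValueError("position lists must align with the token list")


@dataclass
class RelationBag:
    """All intra-sentence instances of one (chemical id, disease id) in one document."""

    doc_id: str
    chemical_id: str
    disease_id: str
    instances: list[IntraInstance]
    label: int
    chem_hyponym: int = 1
    dis_hyponym: int = 1

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("a relation bag must contain at least one instance")
        if self.label not in (0, 1):
            raise ValueError("bag label must be binary")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chemical_id, self.disease_id)


@dataclass
class InterPairInstance:
    """Document-level features of a pair with no single-sentence co-occurrence."""

    doc_id: str
    chemical_id: str
    disease_id: str
    chem_surfaces: list[str]  # normalized tokens of every chemical mention
    dis_surfaces: list[str]
    chem_hyponym: int
    dis_hyponym: int
    chem_freq_bin: int
    dis_freq_bin: int
    label: int
    # nearest mention pair (minimum global token distance), for traceability
    nearest: tuple[Mention, Mention] | None = field(default=None, repr=False)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chemical_id, self.disease_id)


def candidate_pairs(document: Document) -> list[tuple[str, str]]:
    """Cartesian product of the document's distinct chemical and disease ids."""
    chems = document.concept_ids("Chemical")
    dis = document.concept_ids("Disease")
    return [(c, d) for c in chems for d in dis]


def label_pair(
    pair: tuple[str, str], kb: Iterable[KBFact]
) -> int:
    """1 iff the pair is curated in the KB with the positive relation tag."""
    chem, dis = pair
    positive = _positive_pairs(kb)
    return 1 if (chem, dis) in positive else 0


def _positive_pairs(kb: Iterable[KBFact]) -> frozenset[tuple[str, str]]:
    if isinstance(kb, frozenset) and kb and isinstance(next(iter(kb)), tuple):
        return kb  # already an id-pair set
    return frozenset((f.chemical_id, f.disease_id) for f in kb if f.is_positive)


def _mention_anchor(sentence: TokenizedSentence, mention: Mention) -> int:
    return sentence.token_index_at(mention.start)


def _sentence_of(mention: Mention, sentences: Sequence[TokenizedSentence]) -> TokenizedSentence:
    for sent in sentences:
        s, e = sent.char_span
        if s <= mention.start < e:
            return sent
    raise ValueError(f"mention at {mention.start} outside every sentence span")


def build_intra_bags(
    document: Document,
    kb: Iterable[KBFact],
    mesh_tree: dict[str, list[str]] | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    sentences: Sequence[TokenizedSentence] | None = None,
) -> list[RelationBag]:
    """Build one labeled bag per candidate pair with >=1 sentence co-occurrence.

    Every (chemical mention, disease mention) pair co-located in a sentence
    yields one instance carrying normalized tokens, two relative-position code
    lists and the sentence's location marker.
    """
    if sentences is None:
        sentences = segment_and_tokenize(document)
    n_abstract = len(sentences) - 1
    positive = _positive_pairs(kb)
    tags = _document_hyponym_tags(document, mesh_tree)

    by_pair: dict[tuple[str, str], list[IntraInstance]] = {}
    for sent in sentences:
        s, e = sent.char_span
        local = [m for m in document.mentions if s <= m.start < e]
        chems = [m for m in local if m.etype == "Chemical"]
        diss = [m for m in local if m.etype == "Disease"]
        if not chems or not diss:
            continue
        tokens = [normalize_token(t) for t in sent.tokens]
        marker = location_marker(sent, n_abstract)
        for cm in chems:
            pc = relative_positions(len(tokens), _mention_anchor(sent, cm), max_dist)
            for dm in diss:
                pd = relative_positions(len(tokens), _mention_anchor(sent, dm), max_dist)
                inst = IntraInstance(sent.index, cm, dm, tokens, pc, pd, marker)
                by_pair.setdefault((cm.concept_id, dm.concept_id), []).append(inst)

    bags = []
    for (chem, dis) in sorted(by_pair):
        bags.append(
            RelationBag(
                doc_id=document.doc_id,
                chemical_id=chem,
                disease_id=dis,
                instances=by_pair[(chem, dis)],
                label=1 if (chem, dis) in positive else 0,
                chem_hyponym=tags.get(chem, 1),
                dis_hyponym=tags.get(dis, 1),
            )
        )
    return bags


def _document_hyponym_tags(
    document: Document, mesh_tree: dict[str, list[str]] | None
) -> dict[str, int]:
    concepts = {m.concept_id for m in document.mentions}
    if mesh_tree is None:
        return {c: 1 for c in concepts}
    return hyponym_tags(concepts, mesh_tree)


def build_inter_instances(
    document: Document,
    kb: Iterable[KBFact],
    mesh_tree: dict[str, list[str]] | None = None,
    sentences: Sequence[TokenizedSentence] | None = None,
) -> list[InterPairInstance]:
    """One featurized instance per candidate pair with zero sentence co-occurrence.

    The nearest mention pair (minimum absolute global token distance; ties go
    to the earliest chemical mention) is recorded for traceability while the
    lexical features aggregate over all mentions of each entity.
    """
    if sentences is None:
        sentences = segment_and_tokenize(document)
    positive = _positive_pairs(kb)
    tags = _document_hyponym_tags(document, mesh_tree)

    cooccurring: set[tuple[str, str]] = set()
    for sent in sentences:
        s, e = sent.char_span
        local = [m for m in document.mentions if s <= m.start < e]
        for cm in local:
            if cm.etype != "Chemical":
                continue
            for dm in local:
                if dm.etype == "Disease":
                    cooccurring.add((cm.concept_id, dm.concept_id))

    # global token index of each mention's anchor token
    anchor: dict[tuple[int, int], int] = {}
    offset = 0
    for sent in sentences:
        s, e = sent.char_span
        for m in document.mentions:
            if s <= m.start < e:
                anchor[(m.start, m.end)] = offset + _mention_anchor(sent, m)
        offset += len(sent.tokens)

    counts: dict[str, int] = {}
    surfaces: dict[str, list[str]] = {}
    for m in document.mentions:
        counts[m.concept_id] = counts.get(m.concept_id, 0) + 1
        toks = [normalize_token(t) for t in m.surface.split()]
        surfaces.setdefault(m.concept_id, []).extend(toks)

    out = []
    for chem, dis in candidate_pairs(document):
        if (chem, dis) in cooccurring:
            continue
        cms = [m for m in document.mentions if m.concept_id == chem and m.etype == "Chemical"]
        dms = [m for m in document.mentions if m.concept_id == dis and m.etype == "Disease"]
        best = min(
            ((cm, dm) for cm in cms for dm in dms),
            key=lambda p: (
                abs(anchor[(p[0].start, p[0].end)] - anchor[(p[1].start, p[1].end)]),
                p[0].start,
                p[1].start,
            ),
        )
        out.append(
            InterPairInstance(
                doc_id=document.doc_id,
                chemical_id=chem,
                disease_id=dis,
                chem_surfaces=surfaces[chem],
                dis_surfaces=surfaces[dis],
                chem_hyponym=tags.get(chem, 1),
                dis_hyponym=tags.get(dis, 1),
                chem_freq_bin=frequency_bin(counts[chem]),
                dis_freq_bin=frequency_bin(counts[dis]),
                label=1 if (chem, dis) in positive else 0,
                nearest=best,
            )
        )
    return out


def align_document(
    document: Document,
    kb: Iterable[KBFact],
    mesh_tree: dict[str, list[str]] | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
) -> tuple[list[RelationBag], list[InterPairInstance]]:
    """Partition a document's candidate pairs into intra bags and inter instances."""
    sentences = segment_and_tokenize(document)
    positive = _positive_pairs(kb)
    bags = build_intra_bags(document, positive, mesh_tree, max_dist, sentences)
    inter = build_inter_instances(document, positive, mesh_tree, sentences)
    n_pairs = len(candidate_pairs(document))
    if len(bags) + len(inter) != n_pairs:
        raise AssertionError(
            f"{document.doc_id}: alignment does not partition the candidate pairs "
            f"({len(bags)} bags + {len(inter)} inter != {n_pairs})"
        )
    return bags, inter


def align_collection(
    documents: Iterable[Document],
    kb: Iterable[KBFact],
    mesh_tree: dict[str, list[str]] | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
) -> tuple[list[RelationBag], list[InterPairInstance]]:
    positive = _positive_pairs(kb)
    bags: list[RelationBag] = []
    inter: list[InterPairInstance] = []
    for doc in documents:
        b, i = align_document(doc, positive, mesh_tree, max_dist)
        bags.extend(b)
        inter.extend(i)
    return bags, inter


def cap_negatives(items: list, max_ratio: float, seed: int = 0) -> list:
    """Optionally subsample negatives to at most ``max_ratio`` per positive.

    Works on any list of labeled bags or inter instances.  By default
    alignment keeps every non-curated candidate pair; this knob trades recall
    of negatives for class balance.  Order of the kept items is preserved.
    """
    if max_ratio <= 0:
        raise ValueError("max_ratio must be positive")
    import numpy as np

    positives = [x for x in items if x.label == 1]
    negatives = [x for x in items if x.label == 0]
    limit = int(max_ratio * len(positives))
    if len(negatives) <= limit:
        return list(items)
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(len(negatives), size=limit, replace=False).tolist())
    kept_negatives = {id(x) for i, x in enumerate(negatives) if i in keep}
    return [x for x in items if x.label == 1 or id(x) in kept_negatives]


def exclude_documents(
    documents: Iterable[Document], blocklist: Iterable[str]
) -> list[Document]:
    """Drop blocklisted doc ids (e.g. benchmark abstracts) from a collection."""
    block = set(blocklist)
    docs = list(documents)
    present = {d.doc_id for d in docs}
    for missing in sorted(block - present):
        logger.info("blocklisted document %s not present in the collection", missing)
    return [d for d in docs if d.doc_id not in block]


# ---------------------------------------------------------------------------
# Serialization (deterministic JSON-lines dumps, for inspection and caching)
# ---------------------------------------------------------------------------

def bags_to_jsonl(bags: Iterable[RelationBag]) -> str:
    lines = []
    for b in bags:
        lines.append(
            json.dumps(
                {
                    "doc_id": b.doc_id,
                    "chemical_id": b.chemical_id,
                    "disease_id": b.disease_id,
                    "label": b.label,
                    "chem_hyponym": b.chem_hyponym,
                    "dis_hyponym": b.dis_hyponym,
                    "instances": [
                        {
                            "sentence": i.sentence_index,
                            "tokens": i.tokens,
                            "pos_chem": i.pos_chem,
                            "pos_dis": i.pos_dis,
                            "location": i.location.name,
                        }
                        for i in b.instances
                    ],
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def inter_to_jsonl(instances: Iterable[InterPairInstance]) -> str:
    lines = []
    for x in instances:
        lines.append(
            json.dumps(
                {
                    "doc_id": x.doc_id,
                    "chemical_id": x.chemical_id,
                    "disease_id": x.disease_id,
                    "label": x.label,
                    "chem_surfaces": x.chem_surfaces,
                    "dis_surfaces": x.dis_surfaces,
                    "chem_hyponym": x.chem_hyponym,
                    "dis_hyponym": x.dis_hyponym,
                    "chem_freq_bin": x.chem_freq_bin,
                    "dis_freq_bin": x.dis_freq_bin,
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
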