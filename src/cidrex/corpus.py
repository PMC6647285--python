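"""Readers and writers for the plain-text formats the pipeline touches.

The document carrier is the PubTator exchange format: one block per PubMed
abstract with ``pmid|t|title`` and ``pmid|a|abstract`` lines followed by
tab-separated entity-mention lines (pmid, start, end, surface, type, MeSH id).
Knowledge-base facts, MeSH tree numbers, gold pairs and predictions travel as
TSV; pre-trained word vectors use the conventional ``token v1 v2 ...`` text
layout.
"""

from __future__ import annotations

import io
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "Mention",
    "Document",
    "KBFact",
    "DocPrediction",
    "PubTatorParseError",
    "MentionIntegrityError",
    "POSITIVE_RELATION",
    "read_pubtator",
    "write_pubtator",
    "read_kb_facts",
    "write_kb_facts",
    "read_mesh_tree",
    "write_mesh_tree",
    "read_word_vectors",
    "read_predictions",
    "write_predictions",
    "read_gold_pairs",
    "write_gold_pairs",
]

#: Knowledge-base relation tag treated as the positive CID class.
POSITIVE_RELATION = "marker/mechanism"

ENTITY_TYPES = ("Chemical", "Disease")


class PubTatorParseError(ValueError):
    """A line of a PubTator stream does not match the expected grammar."""


class MentionIntegrityError(ValueError):
    """A mention's surface string disagrees with its character offsets."""


@dataclass(frozen=True)
class Mention:
    """An entity mention with 0-based half-open offsets into ``title + " " + abstract``."""

    start: int
    end: int
    surface: str
    etype: str
    concept_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"malformed mention interval [{self.start}, {self.end})")
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not self.concept_id:
            raise ValueError("empty concept id")


@dataclass
class Document:
    """A title+abstract document with entity mentions normalized to MeSH ids.

    ``sentences`` (half-open character intervals over :attr:`text`) is empty
    until the document is segmented by :mod:`cidrex.preprocess`.
    """

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("empty doc_id")
        self.mentions = sorted(self.mentions, key=lambda m: (m.start, m.end))
        n = len(self.text)
        for m in self.mentions:
            if m.end > n:
                raise MentionIntegrityError(
                    f"{self.doc_id}: mention [{m.start},{m.end}) outside text of length {n}"
                )
            if self.text[m.start : m.end] != m.surface:
                raise MentionIntegrityError(
                    f"{self.doc_id}: surface {m.surface!r} != slice "
                    f"{self.text[m.start:m.end]!r} at [{m.start},{m.end})"
                )

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract

    def mentions_of(self, etype: str) -> list[Mention]:
        return [m for m in self.mentions if m.etype == etype]

    def concept_ids(self, etype: str) -> list[str]:
        """Distinct concept ids of one entity type, in sorted order."""
        return sorted({m.concept_id for m in self.mentions if m.etype == etype})


@dataclass(frozen=True)
class KBFact:
    chemical_id: str
    disease_id: str
    relation: str

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.disease_id:
            raise ValueError("KB fact with empty concept id")

    @property
    def is_positive(self) -> bool:
        return self.relation.lower() == POSITIVE_RELATION


@dataclass(frozen=True)
class DocPrediction:
    """A scored document-level <Chemical ID, Disease ID> pair."""

    doc_id: str
    chemical_id: str
    disease_id: str
    score: float
    source: str  # "intra" or "inter"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.source not in ("intra", "inter"):
            raise ValueError(f"unknown prediction source {self.source!r}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


@contextmanager
def _as_text_stream(src: str | IO[str], mode: str = "r") -> Iterator[IO[str]]:
    if isinstance(src, (str,)):
        fh = open(src, mode, encoding="utf-8")
        try:
            yield fh
        finally:
            fh.close()
    else:
        yield src


# ---------------------------------------------------------------------------
# PubTator documents
# ---------------------------------------------------------------------------

def read_pubtator(src: str | IO[str]) -> list[Document]:
    """Parse a PubTator stream into documents.

    Blocks are separated by blank lines; each block carries an ``id|t|`` line,
    an ``id|a|`` line, then tab-separated mention lines.  Raises
    :class:`PubTatorParseError` naming the offending line number, or
    :class:`MentionIntegrityError` when a mention's surface does not equal the
    text slice at its offsets.
    """
    docs: list[Document] = []
    doc_id = title = abstract = None
    mentions: list[Mention] = []

    def flush(lineno: int) -> None:
        nonlocal doc_id, title, abstract, mentions
        if doc_id is None:
            return
        if title is None or abstract is None:
            raise PubTatorParseError(
                f"line {lineno}: block {doc_id!r} is missing a |t| or |a| line"
            )
        docs.append(Document(doc_id, title, abstract, mentions))
        doc_id = title = abstract = None
        mentions = []

    with _as_text_stream(src) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if "|t|" in line or "|a|" in line:
                pid, kind, payload = line.split("|", 2)
                if doc_id is not None and pid != doc_id:
                    raise PubTatorParseError(
                        f"line {lineno}: id {pid!r} inside block {doc_id!r}"
                    )
                doc_id = pid
                if kind == "t":
                    title = payload
                elif kind == "a":
                    abstract = payload
                else:
                    raise PubTatorParseError(f"line {lineno}: unknown line kind {kind!r}")
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PubTatorParseError(
                    f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            pid, start, end, surface, etype, concept_id = fields
            if doc_id is None or pid != doc_id:
                raise PubTatorParseError(
                    f"line {lineno}: mention id {pid!r} outside block {doc_id!r}"
                )
            try:
                mention = Mention(int(start), int(end), surface, etype, concept_id)
            except ValueError as exc:
                if isinstance(exc, MentionIntegrityError):
                    raise
                raise PubTatorParseError(f"line {lineno}: {exc}") from exc
            mentions.append(mention)
        flush(lineno)
    return docs


def write_pubtator(docs: Iterable[Document], dst: str | IO[str]) -> None:
    with _as_text_stream(dst, "w") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in doc.mentions:
                fh.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.etype}\t{m.concept_id}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# KB facts, MeSH tree, gold pairs
# ---------------------------------------------------------------------------

def read_kb_facts(src: str | IO[str]) -> set[KBFact]:
    """Read a chemical/disease/relation TSV; duplicate lines collapse."""
    facts: set[KBFact] = set()
    with _as_text_stream(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PubTatorParseError(
                    f"line {lineno}: expected 3 columns in KB facts TSV, got {len(fields)}"
                )
            facts.add(KBFact(*fields))
    return facts


def write_kb_facts(facts: Iterable[KBFact], dst: str | IO[str]) -> None:
    with _as_text_stream(dst, "w") as fh:
        for f in sorted(facts, key=lambda f: (f.chemical_id, f.disease_id, f.relation)):
            fh.write(f"{f.chemical_id}\t{f.disease_id}\t{f.relation}\n")


def read_mesh_tree(src: str | IO[str]) -> dict[str, list[str]]:
    """Read ``concept_id <TAB> tree_number`` rows into id -> tree-number lists."""
    tree: dict[str, list[str]] = {}
    with _as_text_stream(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[1]:
                raise PubTatorParseError(f"line {lineno}: expected concept_id<TAB>tree_number")
            tree.setdefault(fields[0], []).append(fields[1])
    return tree


def write_mesh_tree(tree: dict[str, list[str]], dst: str | IO[str]) -> None:
    with _as_text_stream(dst, "w") as fh:
        for cid in sorted(tree):
            for tn in tree[cid]:
                fh.write(f"{cid}\t{tn}\n")


def read_gold_pairs(src: str | IO[str]) -> set[tuple[str, str, str]]:
    """Gold document-level pairs as ``doc_id <TAB> chemical_id <TAB> disease_id``."""
    gold: set[tuple[str, str, str]] = set()
    with _as_text_stream(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PubTatorParseError(f"line {lineno}: expected >=3 columns in gold TSV")
            gold.add((fields[0], fields[1], fields[2]))
    return gold


def write_gold_pairs(gold: Iterable[tuple[str, str, str]], dst: str | IO[str]) -> None:
    with _as_text_stream(dst, "w") as fh:
        for t in sorted(gold):
            fh.write("\t".join(t) + "\n")


# ---------------------------------------------------------------------------
# Word vectors and predictions
# ---------------------------------------------------------------------------

def read_word_vectors(src: str | IO[str]) -> dict[str, np.ndarray]:
    """Read a ``token v1 v2 ... vd`` text file into a token -> vector map."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with _as_text_stream(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split()
            if not parts:
                continue
            vec = np.asarray([float(x) for x in parts[1:]], dtype=float)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise PubTatorParseError(
                    f"line {lineno}: vector of length {vec.size}, expected {dim}"
                )
            vectors[parts[0]] = vec
    return vectors


def write_predictions(preds: Iterable[DocPrediction], dst: str | IO[str]) -> None:
    """Write predictions as TSV ordered by doc id, then score descending."""
    rows = sorted(preds, key=lambda p: (p.doc_id, -p.score, p.chemical_id, p.disease_id))
    with _as_text_stream(dst, "w") as fh:
        for p in rows:
            fh.write(
                f"{p.doc_id}\t{p.chemical_id}\t{p.disease_id}\t{p.score:.6f}\t{p.source}\n"
            )


def read_predictions(src: str | IO[str]) -> list[DocPrediction]:
    preds: list[DocPrediction] = []
    with _as_text_stream(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise PubTatorParseError(f"line {lineno}: expected 5 columns in predictions TSV")
            preds.append(
                DocPrediction(fields[0], fields[1], fields[2], float(fields[3]), fields[4])
            )
    return preds


def pubtator_string(docs: Iterable[Document]) -> str:
    """Serialize documents to a PubTator string (convenience for round trips)."""
    buf = io.StringIO()
    write_pubtator(docs, buf)
    return buf.getvalue()
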