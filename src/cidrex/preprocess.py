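"""Text normalization, sentence segmentation and model-facing feature codes.

The models never see raw text: tokens are lowercased, digit runs collapse to a
single ``<num>`` symbol and non-ASCII characters are dropped.  Segmentation is
rule based (deterministic and dependency free) and offset preserving, so
mention offsets computed on the raw text remain valid; token strings are
normalized only after tokenization.

Feature codes computed here:

* relative-position codes of each token to a target entity, clipped to
  ``[-max_dist, +max_dist]``;
* one of four location markers per sentence (title / first / last / middle
  abstract sentence);
* a binary hyponym tag per (document, concept) marking concepts that are the
  most specific of their MeSH lineage present in the document;
* log2 frequency bins of per-document mention counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .corpus import Document, Mention

logger = logging.getLogger(__name__)

__all__ = [
    "LocationMarker",
    "TokenizedSentence",
    "normalize_text",
    "normalize_token",
    "segment_and_tokenize",
    "location_marker",
    "relative_positions",
    "hyponym_tags",
    "frequency_bin",
    "DEFAULT_MAX_DIST",
    "NUM_SYMBOL",
    "UNK_SYMBOL",
]

#: Unified symbol replacing any maximal run of digits.
NUM_SYMBOL = "<num>"
#: Placeholder for tokens whose normalization is empty (e.g. purely non-ASCII).
UNK_SYMBOL = "<unk>"
#: Default clip range for relative-position codes (2 * 30 + 1 = 61 codes).
DEFAULT_MAX_DIST = 30

MAX_FREQUENCY_BIN = 7


class LocationMarker(Enum):
    """Where an instance sentence sits in its document (4 values)."""

    T = 0  # title
    A_FST = 1  # first sentence of the abstract
    A_LST = 2  # last sentence of the abstract
    A_MDL = 3  # middle of the abstract


_NON_PRINTABLE_ASCII = re.compile(r"[^ -~\s]")
_DIGIT_RUN = re.compile(r"[0-9]+")
_WS_RUN = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase, map digit runs to ``<num>``, strip non-ASCII, collapse spaces.

    Idempotent: the output contains no digits, no uppercase letters and no
    characters outside printable ASCII.
    """
    out = _NON_PRINTABLE_ASCII.sub("", text)
    out = out.lower()
    out = _DIGIT_RUN.sub(NUM_SYMBOL, out)
    out = _WS_RUN.sub(" ", out).strip()
    return out


def normalize_token(token: str) -> str:
    """Normalize a single token; empty results map to the ``<unk>`` placeholder."""
    out = normalize_text(token)
    return out if out else UNK_SYMBOL


@dataclass
class TokenizedSentence:
    """A tokenized sentence with character spans kept in document coordinates."""

    tokens: list[str]
    token_spans: list[tuple[int, int]]
    char_span: tuple[int, int]
    index: int
    in_title: bool

    def token_index_at(self, char_offset: int) -> int:
        """Index of the token covering ``char_offset`` (first token at/after it)."""
        for i, (s, e) in enumerate(self.token_spans):
            if s <= char_offset < e:
                return i
        for i, (s, _) in enumerate(self.token_spans):
            if s >= char_offset:
                return i
        raise IndexError(f"offset {char_offset} outside sentence span {self.char_span}")


# Sentence-final punctuation followed by whitespace and an uppercase letter or
# digit opens a boundary candidate; a protected-abbreviation list vetoes it.
_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")
_PROTECTED_ABBREV = frozenset(
    {"i.e", "e.g", "fig", "figs", "etc", "vs", "approx", "dr", "no", "ref", "al"}
)
_TOKEN = re.compile(r"[A-Za-z0-9<>][A-Za-z0-9<>_'-]*|[^\sA-Za-z0-9]")
_LAST_WORD = re.compile(r"[a-z.]+$")


def _is_protected(prefix: str) -> bool:
    """True when the text before a boundary candidate ends in a protected abbreviation."""
    m = _LAST_WORD.search(prefix.lower().rstrip())
    return bool(m) and m.group(0).strip(".") in _PROTECTED_ABBREV


def _split_abstract(abstract: str, offset: int, mentions: list[Mention]) -> list[tuple[int, int]]:
    """Half-open sentence spans of the abstract, in document coordinates."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(abstract):
        end = m.end()  # split just after the punctuation run
        if _is_protected(abstract[start : m.start()]):
            continue
        doc_end = offset + end
        # Suppress boundaries that would cut through an annotated mention.
        if any(mn.start < doc_end and mn.end > doc_end for mn in mentions):
            continue
        spans.append((offset + start, doc_end))
        start = end
        while start < len(abstract) and abstract[start].isspace():
            start += 1
    if start < len(abstract):
        spans.append((offset + start, offset + len(abstract)))
    return spans


def _tokenize_span(text: str, start: int, end: int) -> tuple[list[str], list[tuple[int, int]]]:
    tokens, spans = [], []
    for m in _TOKEN.finditer(text[start:end]):
        tokens.append(m.group(0))
        spans.append((start + m.start(), start + m.end()))
    return tokens, spans


def segment_and_tokenize(document: Document) -> list[TokenizedSentence]:
    """Segment a document into tokenized sentences and record spans on it.

    The title is sentence 0; abstract sentences follow in order.  Boundary
    candidates falling inside an annotated mention are suppressed so mentions
    never straddle sentences.  Token strings are raw; normalize with
    :func:`normalize_token` when building model inputs.
    """
    text = document.text
    spans = [(0, len(document.title))]
    spans += _split_abstract(document.abstract, len(document.title) + 1, document.mentions)
    sentences = []
    for idx, (s, e) in enumerate(spans):
        tokens, token_spans = _tokenize_span(text, s, e)
        sentences.append(
            TokenizedSentence(tokens, token_spans, (s, e), index=idx, in_title=(idx == 0))
        )
    document.sentences = [sent.char_span for sent in sentences]
    return sentences


def location_marker(sentence: TokenizedSentence, n_abstract_sentences: int) -> LocationMarker:
    """Map a sentence to its Table-style location marker.

    Priority on overlap is T > A_Fst > A_Lst > A_Mdl (a one-sentence abstract
    is marked A_Fst).
    """
    if sentence.in_title:
        return LocationMarker.T
    if n_abstract_sentences <= 0:
        raise ValueError("non-title sentence in a document with no abstract sentences")
    if sentence.index == 1:
        return LocationMarker.A_FST
    if sentence.index == n_abstract_sentences:
        return LocationMarker.A_LST
    return LocationMarker.A_MDL


def relative_positions(
    n_tokens: int, anchor_token_index: int, max_dist: int = DEFAULT_MAX_DIST
) -> list[int]:
    """Clipped relative distance of every token to the anchor token.

    ``code[i] = clip(i - anchor, -max_dist, +max_dist)``; the anchor is the
    first token of the target entity mention.
    """
    if not 0 <= anchor_token_index < n_tokens:
        raise IndexError(
            f"anchor {anchor_token_index} outside sentence of {n_tokens} tokens"
        )
    return [
        max(-max_dist, min(max_dist, i - anchor_token_index)) for i in range(n_tokens)
    ]


def hyponym_tags(
    document_concepts: set[str] | list[str], tree: dict[str, list[str]]
) -> dict[str, int]:
    """Tag each concept 1 iff it is most specific among the document's concepts.

    A concept loses the tag when another concept in the same document carries a
    tree number that strictly extends (proper dotted prefix) one of its tree
    numbers.  Concepts absent from the tree default to 1 with a warning.
    """
    concepts = sorted(set(document_concepts))
    tags: dict[str, int] = {}
    for c in concepts:
        if c not in tree:
            logger.warning("concept %s missing from MeSH tree; hyponym tag defaults to 1", c)
            tags[c] = 1
            continue
        most_specific = 1
        for other in concepts:
            if other == c or other not in tree:
                continue
            for tn in tree[c]:
                if any(o.startswith(tn + ".") for o in tree[other]):
                    most_specific = 0
                    break
            if not most_specific:
                break
        tags[c] = most_specific
    return tags


def frequency_bin(mention_count: int) -> int:
    """log2 bucket of a per-document mention count, capped at 7."""
    if mention_count < 1:
        raise ValueError(f"mention count must be >= 1, got {mention_count}")
    return min(int(mention_count).bit_length() - 1, MAX_FREQUENCY_BIN)
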