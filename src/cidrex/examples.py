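"""A tiny real-text fixture: an annotated excerpt of PubMed abstract 10071902.

The excerpt pairs the chemical tetracycline (MeSH D013752) with two diseases:
pseudotumor cerebri (D011559), which co-occurs with the chemical inside single
sentences three times (two chemical mentions in the first sentence, one in the
second), and nausea (D009325), which appears only in a later sentence and so
never co-occurs intra-sententially.  Both pairs are curated Marker/Mechanism
facts, making this the canonical check that alignment builds one
three-instance intra bag and exactly one inter-sentence instance.
"""

from __future__ import annotations

from .corpus import Document, KBFact, Mention, POSITIVE_RELATION

__all__ = ["tetracycline_document", "tetracycline_kb", "PMID"]

PMID = "10071902"

_TITLE = "Tetracycline use and pseudotumor cerebri in children."
_SENTENCES = (
    "Tetracyclines have long been recognized as a cause of pseudotumor cerebri "
    "in adults, but the role of tetracyclines in the pediatric age group has not "
    "been well characterized in the literature and there have been few reported cases.",
    "We retrospectively analyzed the records of all patients admitted with a "
    "diagnosis of pseudotumor cerebri who had documented usage of a "
    "tetracycline-class drug immediately before presentation at the Hospital For "
    "Sick Children in Toronto, Canada, from January 1, 1986, to March 1, 1996.",
    "Symptoms included headache (6 of 6), nausea (5 of 6), and diplopia (4 of 6).",
)

CHEMICAL = "D013752"  # tetracycline
PSEUDOTUMOR = "D011559"
NAUSEA = "D009325"


def tetracycline_document() -> Document:
    """The annotated excerpt as a single PubTator-style document."""
    abstract = " ".join(_SENTENCES)
    text = _TITLE + " " + abstract
    off = len(_TITLE) + 1  # abstract start; title mentions are not annotated

    def at(surface: str, search_from: int) -> tuple[int, int]:
        i = text.index(surface, search_from)
        return i, i + len(surface)

    b_start = off + len(_SENTENCES[0]) + 1
    c_start = b_start + len(_SENTENCES[1]) + 1
    spans = [
        (*at("Tetracyclines", off), "Chemical", CHEMICAL),
        (*at("pseudotumor cerebri", off), "Disease", PSEUDOTUMOR),
        (*at("tetracyclines", off + 1), "Chemical", CHEMICAL),
        (*at("pseudotumor cerebri", b_start), "Disease", PSEUDOTUMOR),
        (*at("tetracycline", b_start + 1), "Chemical", CHEMICAL),
        (*at("nausea", c_start), "Disease", NAUSEA),
    ]
    mentions = [Mention(s, e, text[s:e], t, c) for s, e, t, c in spans]
    return Document(PMID, _TITLE, abstract, mentions)


def tetracycline_kb() -> set[KBFact]:
    """The two curated chemical-disease facts the excerpt aligns against."""
    return {
        KBFact(CHEMICAL, PSEUDOTUMOR, POSITIVE_RELATION),
        KBFact(CHEMICAL, NAUSEA, POSITIVE_RELATION),
    }
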