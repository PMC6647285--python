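"""Seeded synthetic corpora with the statistical structure distant supervision assumes.

The generator emits PubTator-serializable documents, a knowledge base of
planted Marker/Mechanism facts, document-level gold pairs, a toy MeSH tree and
per-instance oracle flags.  Positive pairs that co-occur in a sentence carry a
trigger token strictly between the two mentions in their expressing instances;
a controllable fraction ``bag_noise`` of the remaining instances inside
positive bags are non-expressing (distractor) instances, but every positive
pair keeps at least one expressing instance (the at-least-one assumption).
Pairs routed to the inter-sentence level never share a sentence; for positive
inter pairs both entity mentions carry a shared relational marker token so the
inter-level features are learnable.

Text is templated token sequences, not natural language: the downstream models
consume token and id streams only.  Entity and filler tokens are letter-only
so number normalization cannot collapse them; triggers and distractors all
have the same character length so noise injection can rewrite text in place
without disturbing mention offsets.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import IO

import numpy as np

from .corpus import (
    Document,
    KBFact,
    Mention,
    POSITIVE_RELATION,
    write_gold_pairs,
    write_kb_facts,
    write_mesh_tree,
    write_pubtator,
)

__all__ = ["SynthConfig", "SynthCollection", "generate_collection", "corrupt_bags", "write_collection"]

#: sentence index used in oracle-flag keys for inter-sentence pairs
INTER_SENTENCE = -1

_LEADS = ("Moreover", "Further", "Notably", "Importantly", "Meanwhile", "Subsequently")
_MARKER = "related"  # appended to positive inter-level chemical mentions


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic corpus (all randomness from ``seed``)."""

    n_docs: int = 200
    vocab_size: int = 80
    n_chemicals: int = 25
    n_diseases: int = 25
    mean_sentences: float = 5.0
    positive_pair_rate: float = 0.35
    intra_cooccur_prob: float = 0.65
    bag_noise: float = 0.3  # fraction of non-first positive-bag instances without a trigger
    triggers: tuple[str, ...] = ("induces", "elicits", "evoking", "causing")
    distractors: tuple[str, ...] = ("reports", "studied", "records", "samples", "briefly", "general")
    tree_depth: int = 3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_docs, self.vocab_size, self.n_chemicals, self.n_diseases) <= 0:
            raise ValueError("sizes must be positive")
        for name in ("positive_pair_rate", "intra_cooccur_prob", "bag_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.positive_pair_rate > 0 and (self.n_chemicals == 0 or self.n_diseases == 0):
            raise ValueError("positive pairs require at least one concept of each type")
        if not self.triggers or not self.distractors:
            raise ValueError("trigger and distractor lexicons must be nonempty")


@dataclass
class SynthCollection:
    documents: list[Document]
    kb_facts: set[KBFact]
    gold: set[tuple[str, str, str]]
    mesh_tree: dict[str, list[str]]
    #: (doc_id, chemical_id, disease_id, sentence_index) -> oracle record with
    #: ``expresses`` and, for intra trigger instances, the trigger char span.
    flags: dict[tuple[str, str, str, int], dict]
    #: planted intra instance counts per (doc_id, chemical_id, disease_id)
    expected_intra: dict[tuple[str, str, str], int]
    #: pairs planted with zero sentence co-occurrence
    expected_inter: set[tuple[str, str, str]] = field(default_factory=set)


def _alpha(i: int) -> str:
    """Letter-only base-26 encoding (0 -> 'a', 27 -> 'bb', ...)."""
    s = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s


def _toy_mesh_tree(cfg: SynthConfig, chems: list[str], dis: list[str]) -> dict[str, list[str]]:
    """Dotted codes with planted parent-child chains so both hyponym outcomes occur."""
    tree: dict[str, list[str]] = {}
    for group, prefix in ((chems, "D01"), (dis, "C05")):
        prev_code = None
        for i, cid in enumerate(group):
            if i % 2 == 1 and prev_code is not None and prev_code.count(".") < cfg.tree_depth:
                code = f"{prev_code}.{100 + i}"
            else:
                code = f"{prefix}.{200 + i}"
            tree[cid] = [code]
            prev_code = code
    return tree


def generate_collection(config: SynthConfig) -> SynthCollection:
    """Generate a deterministic corpus + KB + gold + tree + oracle flags."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chems = [f"D{1000 + i}" for i in range(config.n_chemicals)]
    diseases = [f"D{5000 + i}" for i in range(config.n_diseases)]
    chem_tok = {c: f"chem{_alpha(i)}" for i, c in enumerate(chems)}
    dis_tok = {d: f"dis{_alpha(i)}" for i, d in enumerate(diseases)}
    fillers = [f"w{_alpha(i)}" for i in range(config.vocab_size)]
    tree = _toy_mesh_tree(config, chems, diseases)

    # Global knowledge base over the concept grid; a few non-positive facts
    # exercise the "tag preserved but non-positive" path downstream.
    kb: set[KBFact] = set()
    for c in chems:
        for d in diseases:
            if rng.random() < config.positive_pair_rate:
                kb.add(KBFact(c, d, POSITIVE_RELATION))
    if config.positive_pair_rate > 0 and not any(f.is_positive for f in kb):
        kb.add(KBFact(chems[0], diseases[0], POSITIVE_RELATION))
    positive = {(f.chemical_id, f.disease_id) for f in kb if f.is_positive}
    negatives_pool = [(c, d) for c in chems[:5] for d in diseases[:5] if (c, d) not in positive]
    for c, d in negatives_pool[:2]:
        kb.add(KBFact(c, d, "therapeutic"))

    documents: list[Document] = []
    gold: set[tuple[str, str, str]] = set()
    flags: dict[tuple[str, str, str, int], dict] = {}
    expected_intra: dict[tuple[str, str, str], int] = {}
    expected_inter: set[tuple[str, str, str]] = set()

    first_fact = min(positive) if positive else None
    for di in range(config.n_docs):
        doc_id = f"S{10000 + di}"
        n_c = 1 + int(rng.random() < 0.5)
        n_d = 1 + int(rng.random() < 0.5)
        doc_chems = [chems[i] for i in rng.choice(len(chems), size=n_c, replace=False)]
        doc_dis = [diseases[i] for i in rng.choice(len(diseases), size=n_d, replace=False)]
        if di == 0 and first_fact is not None:
            doc_chems[0], doc_dis[0] = first_fact  # guarantee >=1 gold pair overall
        doc_chems = sorted(set(doc_chems))
        doc_dis = sorted(set(doc_dis))

        # sentence plans: (tokens, mentions, pair_key, expresses, trigger_tok_idx)
        # mentions: list of (first_token_idx, n_tokens, concept_id, etype)
        plans: list[dict] = []
        for c in doc_chems:
            for d in doc_dis:
                label = (c, d) in positive
                if label:
                    gold.add((doc_id, c, d))
                if rng.random() < config.intra_cooccur_prob:
                    n_co = 1 + int(rng.integers(0, 3))
                    for k in range(n_co):
                        expresses = bool(label and (k == 0 or rng.random() >= config.bag_noise))
                        mid = (
                            str(rng.choice(config.triggers))
                            if expresses
                            else str(rng.choice(config.distractors))
                        )
                        double = rng.random() < 0.15
                        toks = [str(rng.choice(_LEADS)), str(rng.choice(fillers))]
                        mentions = [(len(toks), 1, c, "Chemical")]
                        toks.append(chem_tok[c])
                        if double:
                            toks.append("with")
                            mentions.append((len(toks), 1, c, "Chemical"))
                            toks.append(chem_tok[c])
                        mid_idx = len(toks)
                        toks.append(mid)
                        mentions.append((len(toks), 1, d, "Disease"))
                        toks.append(dis_tok[d])
                        toks.append(str(rng.choice(fillers)))
                        toks.append(".")
                        plans.append(
                            dict(
                                tokens=toks,
                                mentions=mentions,
                                pair=(c, d),
                                expresses=expresses,
                                trigger_idx=mid_idx if expresses else None,
                            )
                        )
                        key = (doc_id, c, d)
                        expected_intra[key] = expected_intra.get(key, 0) + (2 if double else 1)
                else:
                    expected_inter.add((doc_id, c, d))
                    # chemical sentence (marker token joins the mention if positive)
                    toks = [str(rng.choice(_LEADS)), str(rng.choice(fillers))]
                    n_tok = 2 if label else 1
                    mentions = [(len(toks), n_tok, c, "Chemical")]
                    toks.append(chem_tok[c])
                    if label:
                        toks.append(_MARKER)
                    toks += [str(rng.choice(fillers)), "."]
                    plans.append(dict(tokens=toks, mentions=mentions, pair=None))
                    # disease sentence (marker joins the mention if positive)
                    toks = [str(rng.choice(_LEADS)), str(rng.choice(fillers))]
                    mentions = [(len(toks), n_tok, d, "Disease")]
                    toks.append(dis_tok[d])
                    if label:
                        toks.append(_MARKER)
                    toks += [str(rng.choice(fillers)), "."]
                    plans.append(dict(tokens=toks, mentions=mentions, pair=None))
                    flags[(doc_id, c, d, INTER_SENTENCE)] = {
                        "expresses": bool(label),
                        "trigger_span": None,
                    }

        # title: occasionally promote an intra co-occurrence plan, else filler
        title_plan = None
        intra_plans = [p for p in plans if p["pair"] is not None]
        if intra_plans and rng.random() < 0.25:
            title_plan = intra_plans[0]
            plans.remove(title_plan)
            title_plan["tokens"] = title_plan["tokens"][:-1]  # titles carry no final period
        n_abstract = max(2, int(rng.poisson(config.mean_sentences)), len(plans))
        while len(plans) < n_abstract:
            toks = [str(rng.choice(_LEADS))] + [
                str(rng.choice(fillers)) for _ in range(int(rng.integers(3, 6)))
            ] + ["."]
            plans.append(dict(tokens=toks, mentions=[], pair=None))
        plans = [plans[i] for i in rng.permutation(len(plans))]

        if title_plan is None:
            title_plan = dict(
                tokens=["Observations", "on", str(rng.choice(fillers)), "cohorts"],
                mentions=[],
                pair=None,
            )

        doc = _assemble_document(doc_id, title_plan, plans, flags)
        documents.append(doc)

    return SynthCollection(
        documents=documents,
        kb_facts=kb,
        gold=gold,
        mesh_tree=tree,
        flags=flags,
        expected_intra=expected_intra,
        expected_inter=expected_inter,
    )


def _assemble_document(
    doc_id: str,
    title_plan: dict,
    abstract_plans: list[dict],
    flags: dict,
) -> Document:
    """Join sentence plans into text, computing mention offsets and flag spans."""
    mentions: list[Mention] = []
    pieces: list[str] = []
    cursor = 0

    def emit(plan: dict, sent_index: int) -> str:
        nonlocal cursor
        starts = []
        s = ""
        for tok in plan["tokens"]:
            if s:
                s += " "
            starts.append(cursor + len(s))
            s += tok
        for first, n_tok, cid, etype in plan["mentions"]:
            m_start = starts[first]
            m_end = starts[first + n_tok - 1] + len(plan["tokens"][first + n_tok - 1])
            mentions.append((m_start, m_end, cid, etype))
        if plan["pair"] is not None:
            c, d = plan["pair"]
            span = None
            if plan["trigger_idx"] is not None:
                ti = plan["trigger_idx"]
                span = (starts[ti], starts[ti] + len(plan["tokens"][ti]))
            key = (doc_id, c, d, sent_index)
            flags[key] = {"expresses": plan["expresses"], "trigger_span": span}
        return s

    title = emit(title_plan, 0)
    cursor = len(title) + 1
    for i, plan in enumerate(abstract_plans, start=1):
        piece = emit(plan, i)
        pieces.append(piece)
        cursor += len(piece) + 1
    abstract = " ".join(pieces)
    text = title + " " + abstract
    ms = [Mention(s, e, text[s:e], etype, cid) for (s, e, cid, etype) in mentions]
    return Document(doc_id, title, abstract, ms)


def corrupt_bags(collection: SynthCollection, nu: float, seed: int = 0) -> SynthCollection:
    """Rewrite a fraction ``nu`` of expressing intra instances into distractors.

    Triggers are replaced in place by an equal-length distractor token, so all
    offsets stay valid.  One expressing instance per positive pair is protected
    to preserve the at-least-one guarantee; if ``nu`` demands more rewrites
    than the unprotected pool allows, the call is refused.
    """
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")
    out = copy.deepcopy(collection)
    if nu == 0.0:
        return out
    rng = np.random.default_rng(seed)

    expressing = sorted(
        k
        for k, v in out.flags.items()
        if k[3] != INTER_SENTENCE and v["expresses"] and v["trigger_span"] is not None
    )
    protected = {}
    for key in expressing:
        pair = key[:3]
        if pair not in protected or key[3] < protected[pair][3]:
            protected[pair] = key
    pool = [k for k in expressing if protected[k[:3]] != k]
    n_rewrite = int(round(nu * len(expressing)))
    if n_rewrite > len(pool):
        raise ValueError(
            f"cannot rewrite {n_rewrite} of {len(expressing)} expressing instances "
            f"without breaking the at-least-one guarantee (pool of {len(pool)})"
        )
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_rewrite, replace=False)]

    docs = {d.doc_id: d for d in out.documents}
    distractor_by_len: dict[int, list[str]] = {}
    # reuse the default lexicon; equal-length replacement keeps offsets intact
    for dtok in SynthConfig().distractors:
        distractor_by_len.setdefault(len(dtok), []).append(dtok)
    for key in chosen:
        doc = docs[key[0]]
        s, e = out.flags[key]["trigger_span"]
        candidates = distractor_by_len.get(e - s)
        if not candidates:
            raise ValueError(f"no distractor of length {e - s} available for in-place rewrite")
        repl = candidates[int(rng.integers(0, len(candidates)))]
        text = doc.text
        new_text = text[:s] + repl + text[s:][e - s :]
        nt = len(doc.title)
        new_doc = Document(
            doc.doc_id, new_text[:nt], new_text[nt + 1 :], list(doc.mentions)
        )
        docs[key[0]] = new_doc
        out.flags[key] = {"expresses": False, "trigger_span": None}
    out.documents = [docs[d.doc_id] for d in out.documents]
    return out


def write_collection(collection: SynthCollection, outdir: str) -> None:
    """Write docs.pubtator, kb.tsv, mesh.tsv, gold.tsv and flags.jsonl to a directory."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_pubtator(collection.documents, os.path.join(outdir, "docs.pubtator"))
    write_kb_facts(collection.kb_facts, os.path.join(outdir, "kb.tsv"))
    write_mesh_tree(collection.mesh_tree, os.path.join(outdir, "mesh.tsv"))
    write_gold_pairs(collection.gold, os.path.join(outdir, "gold.tsv"))
    with open(os.path.join(outdir, "flags.jsonl"), "w", encoding="utf-8") as fh:
        _write_flags(collection, fh)


def _write_flags(collection: SynthCollection, fh: IO[str]) -> None:
    for key in sorted(collection.flags):
        rec = collection.flags[key]
        fh.write(
            json.dumps(
                {
                    "doc_id": key[0],
                    "chemical_id": key[1],
                    "disease_id": key[2],
                    "sentence": key[3],
                    "expresses": rec["expresses"],
                    "trigger_span": rec["trigger_span"],
                },
                sort_keys=True,
            )
            + "\n"
        )
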