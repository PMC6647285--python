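"""End-to-end glue: align, train both levels, predict, merge and score.

`run_synthetic_experiment` is the package's reference experiment: it generates
a seeded synthetic collection, splits it by document, trains the intra
attention model and the inter autoencoder on the training split, and reports
document-level precision/recall/F1 of the merged predictions on the held-out
split, together with per-level scores and the attention discrimination
statistics enabled by the generator's oracle flags.  Model dimensions default
to a compact configuration sized for single-CPU runs on synthetic corpora;
production-scale dimensions remain the estimator defaults.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .align import InterPairInstance, RelationBag, align_collection
from .corpus import Document, DocPrediction, KBFact
from .evaluate import evaluate_prf, merge_predictions
from .intra import IntraAttentionClassifier, predict_intra
from .inter import InterAutoencoderClassifier, predict_inter
from .simulate import INTER_SENTENCE, SynthCollection, SynthConfig, generate_collection

__all__ = [
    "SMALL_INTRA",
    "SMALL_INTER",
    "extract_document_relations",
    "attention_discrimination",
    "run_synthetic_experiment",
]

#: compact model dimensions used for synthetic-corpus experiments
SMALL_INTRA = dict(
    word_dim=32,
    position_dim=8,
    identifier_dim=16,
    hyponym_dim=8,
    location_dim=8,
    hidden_dim=24,
    attention_dim=16,
    hidden_nodes=32,
    batch_size=32,
    n_epochs=10,
)
SMALL_INTER = dict(
    word_dim=16,
    identifier_dim=16,
    hyponym_dim=4,
    frequency_dim=4,
    encoder_nodes=16,
    decoder_nodes=8,
    batch_size=64,
    l2=3e-3,
    n_epochs=60,
    patience=20,
)


def extract_document_relations(
    documents: Iterable[Document],
    intra_model: IntraAttentionClassifier,
    inter_model: InterAutoencoderClassifier,
    mesh_tree: dict[str, list[str]] | None = None,
    threshold: float = 0.5,
) -> list[DocPrediction]:
    """Predict merged document-level CID pairs for unlabeled documents."""
    bags, inter = align_collection(documents, frozenset(), mesh_tree)
    return merge_predictions(
        predict_intra(bags, intra_model),
        predict_inter(inter, inter_model),
        threshold=threshold,
    )


def attention_discrimination(
    model: IntraAttentionClassifier,
    bags: list[RelationBag],
    flags: dict[tuple[str, str, str, int], dict],
) -> tuple[float, float]:
    """Mean attention weight on expressing vs noise instances of mixed positive bags.

    Only bags containing both an expressing and a non-expressing instance are
    informative (attention over a homogeneous bag carries no signal).
    """
    expressing, noise = [], []
    for bag in bags:
        if bag.label != 1 or len(bag.instances) < 2:
            continue
        marks = []
        for inst in bag.instances:
            key = (bag.doc_id, bag.chemical_id, bag.disease_id, inst.sentence_index)
            rec = flags.get(key)
            marks.append(None if rec is None else bool(rec["expresses"]))
        if True not in marks or False not in marks:
            continue
        alpha = model.bag_attention(bag)
        for a, m in zip(alpha, marks):
            if m is True:
                expressing.append(a)
            elif m is False:
                noise.append(a)
    if not expressing or not noise:
        raise ValueError("no mixed positive bags available for the attention comparison")
    return float(np.mean(expressing)), float(np.mean(noise))


def _split_documents(
    collection: SynthCollection, test_fraction: float, rng: np.random.Generator
) -> tuple[list[Document], list[Document]]:
    docs = list(collection.documents)
    order = rng.permutation(len(docs))
    n_test = max(1, int(round(test_fraction * len(docs))))
    test_idx = set(order[:n_test].tolist())
    train = [d for i, d in enumerate(docs) if i not in test_idx]
    test = [d for i, d in enumerate(docs) if i in test_idx]
    return train, test


def run_synthetic_experiment(
    seed: int = 0,
    config: SynthConfig | None = None,
    test_fraction: float = 0.2,
    intra_kwargs: dict | None = None,
    inter_kwargs: dict | None = None,
) -> dict:
    """Full distant-supervision experiment on a synthetic collection.

    Returns a dict with the collection, fitted models, per-level held-out
    scores, merged document-level metrics and attention statistics.
    """
    if config is None:
        config = SynthConfig(seed=seed)
    collection = generate_collection(config)
    rng = np.random.default_rng(seed + 1)
    train_docs, test_docs = _split_documents(collection, test_fraction, rng)

    kb, tree = collection.kb_facts, collection.mesh_tree
    train_bags, train_inter = align_collection(train_docs, kb, tree)
    test_bags, test_inter = align_collection(test_docs, kb, tree)

    intra_model = IntraAttentionClassifier(
        **{**SMALL_INTRA, **(intra_kwargs or {})}, random_state=seed
    ).fit(train_bags)
    inter_model = InterAutoencoderClassifier(
        **{**SMALL_INTER, **(inter_kwargs or {})}, random_state=seed
    ).fit(train_inter)

    intra_preds = predict_intra(test_bags, intra_model)
    inter_preds = predict_inter(test_inter, inter_model)
    merged = merge_predictions(intra_preds, inter_preds)
    test_ids = {d.doc_id for d in test_docs}
    gold_test = {g for g in collection.gold if g[0] in test_ids}
    merged_eval = evaluate_prf(merged, gold_test)

    intra_gold = {(b.doc_id, b.chemical_id, b.disease_id) for b in test_bags if b.label}
    intra_eval = evaluate_prf([p for p in intra_preds if p.score >= 0.5], intra_gold)
    inter_labels = np.array([x.label for x in test_inter])
    inter_acc = float(
        np.mean(inter_model.predict(test_inter) == inter_labels)
    ) if len(test_inter) else float("nan")

    alpha_expr, alpha_noise = attention_discrimination(
        intra_model, train_bags, collection.flags
    )

    return {
        "collection": collection,
        "train_docs": train_docs,
        "test_docs": test_docs,
        "intra_model": intra_model,
        "inter_model": inter_model,
        "train_bags": train_bags,
        "train_inter": train_inter,
        "test_bags": test_bags,
        "test_inter": test_inter,
        "merged": merged,
        "merged_eval": merged_eval,
        "intra_eval": intra_eval,
        "inter_accuracy": inter_acc,
        "alpha_expressing": alpha_expr,
        "alpha_noise": alpha_noise,
        "intra_loss_curve": intra_model.loss_curve_,
        "inter_loss_curve": inter_model.loss_curve_,
    }
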