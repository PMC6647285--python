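"""Stacked auto-encoder classifier for inter-sentence chemical-disease pairs.

Pairs that never co-occur in a sentence are represented by document-level
lexical features only: per entity, the average word embedding of all its
mention tokens, a concept embedding (identifier + hyponym tag) and a
frequency-bin embedding.  The concatenated feature vector runs through a tanh
encoder, a tanh decoder (with inverted dropout in training only) and a 2-way
softmax.  Despite the auto-encoder name the stack is trained purely
supervised, with the same penalized negative-log-likelihood objective and
RMSprop as the intra model; gradients are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import (
    LOG_FLOOR,
    RMSProp,
    dropout_mask,
    l2_norm_sq,
    softmax,
    uniform_init,
    zeros_like_params,
)
from .align import InterPairInstance
from .corpus import DocPrediction
from .preprocess import MAX_FREQUENCY_BIN, UNK_SYMBOL

__all__ = [
    "InterAutoencoderClassifier",
    "train_inter",
    "predict_inter",
    "init_inter_params",
    "featurize_pair",
    "forward_inter",
    "inter_loss",
    "inter_loss_and_grads",
    "PairData",
]

UNK_CONCEPT = "<unk-id>"


@dataclass
class PairData:
    """Index-encoded inter-sentence pair."""

    chem_tokens: np.ndarray  # indices into D, all mention tokens of the chemical
    dis_tokens: np.ndarray
    chem_idx: int
    dis_idx: int
    chem_tag: int
    dis_tag: int
    chem_freq: int
    dis_freq: int
    label: int = 0


def init_inter_params(
    rng: np.random.Generator,
    n_words: int,
    n_concepts: int,
    word_dim: int = 300,
    identifier_dim: int = 100,
    hyponym_dim: int = 50,
    frequency_dim: int = 50,
    encoder_nodes: int = 250,
    decoder_nodes: int = 50,
) -> dict[str, np.ndarray]:
    """Lookup tables D/F/G/M plus encoder, decoder and output layers."""
    feat_dim = 2 * (word_dim + identifier_dim + hyponym_dim + frequency_dim)
    return {
        "D": rng.normal(0.0, 0.01, size=(word_dim, n_words)),
        "F": rng.normal(0.0, 0.01, size=(identifier_dim, n_concepts)),
        "G": rng.normal(0.0, 0.01, size=(hyponym_dim, 2)),
        "M": rng.normal(0.0, 0.01, size=(frequency_dim, MAX_FREQUENCY_BIN + 1)),
        "W3": uniform_init(rng, (encoder_nodes, feat_dim)),
        "b3": np.zeros(encoder_nodes),
        "W4": uniform_init(rng, (decoder_nodes, encoder_nodes)),
        "b4": np.zeros(decoder_nodes),
        "W5": uniform_init(rng, (2, decoder_nodes)),
        "b5": np.zeros(2),
    }


def featurize_pair(pair: PairData, params: dict[str, np.ndarray]) -> np.ndarray:
    """Feature vector l = [mention; concept; frequency] parts for both entities.

    The mention part averages the word-table columns over every token of every
    mention of the entity (hence invariant to mention order).
    """
    if len(pair.chem_tokens) == 0 or len(pair.dis_tokens) == 0:
        raise ValueError("an entity with zero mention tokens cannot be featurized")
    parts = []
    for toks, cid, tag, freq in (
        (pair.chem_tokens, pair.chem_idx, pair.chem_tag, pair.chem_freq),
        (pair.dis_tokens, pair.dis_idx, pair.dis_tag, pair.dis_freq),
    ):
        parts.append(params["D"][:, toks].mean(axis=1))
        parts.append(params["F"][:, cid])
        parts.append(params["G"][:, tag])
        parts.append(params["M"][:, freq])
    return np.concatenate(parts)


def forward_inter(
    l: np.ndarray,
    params: dict[str, np.ndarray],
    train_mode: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Encoder a = tanh(W3 l + b3), decoder j = tanh(W4 a + b4), softmax output.

    Dropout acts on the decoder output ``j`` during training only.
    """
    if l.shape[0] != params["W3"].shape[1]:
        raise ValueError("feature vector does not match the encoder input size")
    a = np.tanh(params["W3"] @ l + params["b3"])
    j = np.tanh(params["W4"] @ a + params["b4"])
    mask = None
    if train_mode and dropout > 0.0:
        if rng is None:
            raise ValueError("train-mode dropout requires an RNG")
        mask = dropout_mask(rng, j.shape[0], dropout)
    jd = j * mask if mask is not None else j
    o = softmax(params["W5"] @ jd + params["b5"])
    return o, {"l": l, "a": a, "j": j, "jd": jd, "mask": mask, "o": o}


def _backward_pair(
    pair: PairData,
    params: dict[str, np.ndarray],
    trace: dict,
    dlogits: np.ndarray,
    grads: dict[str, np.ndarray],
) -> None:
    grads["W5"] += np.outer(dlogits, trace["jd"])
    grads["b5"] += dlogits
    djd = params["W5"].T @ dlogits
    if trace["mask"] is not None:
        djd = djd * trace["mask"]
    j = trace["j"]
    dpre4 = djd * (1.0 - j * j)
    grads["W4"] += np.outer(dpre4, trace["a"])
    grads["b4"] += dpre4
    da = params["W4"].T @ dpre4
    a = trace["a"]
    dpre3 = da * (1.0 - a * a)
    grads["W3"] += np.outer(dpre3, trace["l"])
    grads["b3"] += dpre3
    dl = params["W3"].T @ dpre3

    word_dim = params["D"].shape[0]
    ident_dim = params["F"].shape[0]
    hyp_dim = params["G"].shape[0]
    freq_dim = params["M"].shape[0]
    block = word_dim + ident_dim + hyp_dim + freq_dim
    for half, (toks, cid, tag, freq) in enumerate(
        (
            (pair.chem_tokens, pair.chem_idx, pair.chem_tag, pair.chem_freq),
            (pair.dis_tokens, pair.dis_idx, pair.dis_tag, pair.dis_freq),
        )
    ):
        off = half * block
        dm = dl[off : off + word_dim] / len(toks)
        for t in toks:
            grads["D"][:, t] += dm
        grads["F"][:, cid] += dl[off + word_dim : off + word_dim + ident_dim]
        grads["G"][:, tag] += dl[
            off + word_dim + ident_dim : off + word_dim + ident_dim + hyp_dim
        ]
        grads["M"][:, freq] += dl[off + word_dim + ident_dim + hyp_dim : off + block]


def inter_loss(
    pairs: list[PairData], params: dict[str, np.ndarray], l2: float = 0.0
) -> float:
    """Mean negative log likelihood of the pair labels plus λ‖θ‖² (no dropout)."""
    if not pairs:
        raise ValueError("empty batch")
    total = 0.0
    for pair in pairs:
        o, _ = forward_inter(featurize_pair(pair, params), params)
        total -= np.log(max(o[pair.label], LOG_FLOOR))
    return total / len(pairs) + l2 * l2_norm_sq(params)


def inter_loss_and_grads(
    pairs: list[PairData],
    params: dict[str, np.ndarray],
    l2: float = 0.0,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    if not pairs:
        raise ValueError("empty batch")
    grads = zeros_like_params(params)
    total = 0.0
    m = len(pairs)
    for pair in pairs:
        o, trace = forward_inter(
            featurize_pair(pair, params), params, train_mode=True, dropout=dropout, rng=rng
        )
        total -= np.log(max(o[pair.label], LOG_FLOOR))
        dlogits = o.copy()
        dlogits[pair.label] -= 1.0
        _backward_pair(pair, params, trace, dlogits / m, grads)
    loss = total / m + l2 * l2_norm_sq(params)
    if l2:
        for k, v in params.items():
            grads[k] += 2.0 * l2 * v
    return loss, grads


class InterAutoencoderClassifier(ClassifierMixin, BaseEstimator):
    """Supervised stacked auto-encoder over inter-sentence pair features.

    Defaults follow the production hyper-parameters (learning rate 0.008,
    batch 400, 300/100/50-d word / identifier / hyponym embeddings, 250
    encoder and 50 decoder nodes, dropout 0.3); the frequency-embedding
    dimension and L2 factor are package choices.
    """

    def __init__(
        self,
        learning_rate: float = 0.008,
        batch_size: int = 400,
        word_dim: int = 300,
        identifier_dim: int = 100,
        hyponym_dim: int = 50,
        frequency_dim: int = 50,
        encoder_nodes: int = 250,
        decoder_nodes: int = 50,
        dropout: float = 0.3,
        l2: float = 1e-4,
        n_epochs: int = 20,
        validation_fraction: float = 0.1,
        patience: int = 3,
        word_vectors: dict[str, np.ndarray] | None = None,
        random_state: int | None = 0,
    ) -> None:
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.word_dim = word_dim
        self.identifier_dim = identifier_dim
        self.hyponym_dim = hyponym_dim
        self.frequency_dim = frequency_dim
        self.encoder_nodes = encoder_nodes
        self.decoder_nodes = decoder_nodes
        self.dropout = dropout
        self.l2 = l2
        self.n_epochs = n_epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.word_vectors = word_vectors
        self.random_state = random_state

    def _build_vocab(self, insts: list[InterPairInstance]) -> None:
        words = sorted({t for x in insts for t in (*x.chem_surfaces, *x.dis_surfaces)})
        concepts = sorted({c for x in insts for c in (x.chemical_id, x.disease_id)})
        self.word_index_ = {UNK_SYMBOL: 0}
        for w in words:
            self.word_index_.setdefault(w, len(self.word_index_))
        self.concept_index_ = {UNK_CONCEPT: 0}
        for c in concepts:
            self.concept_index_.setdefault(c, len(self.concept_index_))

    def _encode(self, x: InterPairInstance) -> PairData:
        wi, ci = self.word_index_, self.concept_index_
        return PairData(
            chem_tokens=np.array([wi.get(t, 0) for t in x.chem_surfaces], dtype=np.intp),
            dis_tokens=np.array([wi.get(t, 0) for t in x.dis_surfaces], dtype=np.intp),
            chem_idx=ci.get(x.chemical_id, 0),
            dis_idx=ci.get(x.disease_id, 0),
            chem_tag=x.chem_hyponym,
            dis_tag=x.dis_hyponym,
            chem_freq=x.chem_freq_bin,
            dis_freq=x.dis_freq_bin,
            label=x.label,
        )

    def fit(self, X: list[InterPairInstance], y=None) -> "InterAutoencoderClassifier":
        insts = list(X)
        labels = (
            np.asarray(y, dtype=int)
            if y is not None
            else np.array([x.label for x in insts], dtype=int)
        )
        if len(labels) != len(insts):
            raise ValueError("y length does not match the number of instances")
        if len(set(labels.tolist())) < 2:
            raise ValueError("training requires both classes to be present")
        rng = np.random.default_rng(self.random_state)
        self._build_vocab(insts)
        self.classes_ = np.array([0, 1])
        params = init_inter_params(
            rng,
            n_words=len(self.word_index_),
            n_concepts=len(self.concept_index_),
            word_dim=self.word_dim,
            identifier_dim=self.identifier_dim,
            hyponym_dim=self.hyponym_dim,
            frequency_dim=self.frequency_dim,
            encoder_nodes=self.encoder_nodes,
            decoder_nodes=self.decoder_nodes,
        )
        if self.word_vectors:
            for tok, vec in self.word_vectors.items():
                jx = self.word_index_.get(tok)
                if jx is not None and len(vec) == self.word_dim:
                    params["D"][:, jx] = vec

        data = [self._encode(x) for x in insts]
        for pd, lab in zip(data, labels):
            pd.label = int(lab)
        order = rng.permutation(len(data))
        n_dev = (
            int(round(self.validation_fraction * len(data)))
            if self.validation_fraction > 0
            else 0
        )
        dev = [data[i] for i in order[:n_dev]]
        train = [data[i] for i in order[n_dev:]]
        if len({p.label for p in train}) < 2:
            train, dev = data, []

        opt = RMSProp(params, self.learning_rate)
        self.loss_curve_ = []
        self.validation_curve_ = []
        best_dev = np.inf
        best_params = None
        stall = 0
        for _ in range(self.n_epochs):
            idx = rng.permutation(len(train))
            epoch_loss = 0.0
            for start in range(0, len(train), self.batch_size):
                batch = [train[i] for i in idx[start : start + self.batch_size]]
                loss, grads = inter_loss_and_grads(
                    batch, params, l2=self.l2, dropout=self.dropout, rng=rng
                )
                opt.step(params, grads)
                epoch_loss += loss * len(batch)
            self.loss_curve_.append(epoch_loss / len(train))
            if dev:
                dev_loss = inter_loss(dev, params, l2=0.0)
                self.validation_curve_.append(dev_loss)
                if dev_loss < best_dev - 1e-6:
                    best_dev = dev_loss
                    best_params = {k: v.copy() for k, v in params.items()}
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        self.params_ = best_params if best_params is not None else params
        return self

    def predict_proba(self, X: list[InterPairInstance]) -> np.ndarray:
        probs = np.empty((len(X), 2))
        for i, x in enumerate(X):
            pd = self._encode(x)
            probs[i], _ = forward_inter(featurize_pair(pd, self.params_), self.params_)
        return probs

    def predict(self, X: list[InterPairInstance]) -> np.ndarray:
        if not len(X):
            return np.zeros(0, dtype=int)
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def save(self, path: str) -> None:
        import json

        meta = {
            "kind": "inter",
            "config": {
                k: v for k, v in self.get_params().items() if k != "word_vectors"
            },
            "word_index": self.word_index_,
            "concept_index": self.concept_index_,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params_)

    @classmethod
    def load(cls, path: str) -> "InterAutoencoderClassifier":
        import json

        with np.load(path, allow_pickle=False) as blob:
            meta = json.loads(str(blob["__meta__"]))
            params = {k: blob[k] for k in blob.files if k != "__meta__"}
        est = cls(**meta["config"])
        est.params_ = params
        est.word_index_ = meta["word_index"]
        est.concept_index_ = meta["concept_index"]
        est.classes_ = np.array([0, 1])
        return est


def train_inter(instances: list[InterPairInstance], **config) -> InterAutoencoderClassifier:
    """Fit an :class:`InterAutoencoderClassifier` on labeled pair instances."""
    return InterAutoencoderClassifier(**config).fit(instances)


def predict_inter(
    instances: list[InterPairInstance], model: InterAutoencoderClassifier
) -> list[DocPrediction]:
    """Score inter pairs as document-level predictions (positive iff >= 0.5)."""
    if not instances:
        return []
    scores = model.predict_proba(instances)[:, 1]
    return [
        DocPrediction(x.doc_id, x.chemical_id, x.disease_id, float(s), "inter")
        for x, s in zip(instances, scores)
    ]
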