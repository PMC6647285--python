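"""Instance-level attention model for intra-sentence bag classification.

Each instance (a sentence with one chemical and one disease mention) is
embedded as a sequence of joint word+position vectors, encoded by a
bidirectional LSTM and mean-pooled into an instance representation ``s``.  An
attention unit scores every instance of a bag against its location embedding
``m`` and the entity-difference embedding ``r = c1 - c2`` of the pair's
concept embeddings; the softmax-normalized scores weight the instances into a
bag representation ``u``.  The feature vector ``[c1; c2; u]`` passes through a
tanh hidden layer (with inverted dropout during training only) and a 2-way
softmax.  Training minimizes the mean negative log likelihood of the weak bag
labels plus an L2 penalty, via RMSprop; all gradients are analytic.

The model is exposed as the sklearn-style :class:`IntraAttentionClassifier`;
``train_intra`` / ``predict_intra`` are thin wrappers over it.
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
    sigmoid,
    softmax,
    uniform_init,
    zeros_like_params,
)
from .align import RelationBag
from .corpus import DocPrediction
from .preprocess import DEFAULT_MAX_DIST, UNK_SYMBOL

__all__ = [
    "IntraAttentionClassifier",
    "train_intra",
    "predict_intra",
    "init_intra_params",
    "embed_instance",
    "lstm_step",
    "encode_instance",
    "concept_embedding",
    "entity_difference",
    "attention_weights",
    "classify_bag",
    "intra_loss",
    "intra_loss_and_grads",
    "BagData",
]

UNK_CONCEPT = "<unk-id>"

_GATE_KEYS = ("Wi", "Ui", "bi", "Wf", "Uf", "bf", "Wo", "Uo", "bo", "Wg", "Ug", "bg")


@dataclass
class BagData:
    """Index-encoded bag: the only input shape the numerical core consumes.

    ``insts`` holds one tuple per instance: word indices, chemical- and
    disease-relative position indices (already shifted by ``max_dist`` into
    ``[0, 2*max_dist]``), and the location-marker index.
    """

    insts: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]]
    chem_idx: int
    chem_tag: int
    dis_idx: int
    dis_tag: int
    label: int = 0


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def init_intra_params(
    rng: np.random.Generator,
    n_words: int,
    n_concepts: int,
    word_dim: int = 300,
    position_dim: int = 50,
    identifier_dim: int = 100,
    hyponym_dim: int = 50,
    location_dim: int = 50,
    hidden_dim: int = 200,
    attention_dim: int = 100,
    hidden_nodes: int = 250,
    max_dist: int = DEFAULT_MAX_DIST,
) -> dict[str, np.ndarray]:
    """Randomly initialize every lookup table and weight of the model.

    Tables store one column per vocabulary entry (word table ``T``, position
    table ``P`` shared by the chemical- and disease-relative codes, location
    table ``L`` with 4 columns, identifier table ``E``, hyponym table ``Q``
    with 2 columns).
    """
    dx = word_dim + 2 * position_dim
    concept_dim = identifier_dim + hyponym_dim
    p: dict[str, np.ndarray] = {
        "T": rng.normal(0.0, 0.01, size=(word_dim, n_words)),
        "P": rng.normal(0.0, 0.01, size=(position_dim, 2 * max_dist + 1)),
        "L": rng.normal(0.0, 0.01, size=(location_dim, 4)),
        "E": rng.normal(0.0, 0.01, size=(identifier_dim, n_concepts)),
        "Q": rng.normal(0.0, 0.01, size=(hyponym_dim, 2)),
        "Ws": uniform_init(rng, (attention_dim, 2 * hidden_dim)),
        "Wm": uniform_init(rng, (attention_dim, location_dim)),
        "Wr": uniform_init(rng, (attention_dim, concept_dim)),
        "bs": np.zeros(attention_dim),
        "v": uniform_init(rng, (attention_dim,)),
        "W1": uniform_init(rng, (hidden_nodes, 2 * concept_dim + 2 * hidden_dim)),
        "b1": np.zeros(hidden_nodes),
        "W2": uniform_init(rng, (2, hidden_nodes)),
        "b2": np.zeros(2),
    }
    for d in ("f", "b"):
        for g in ("i", "f", "o", "g"):
            p[f"{d}_W{g}"] = uniform_init(rng, (hidden_dim, dx))
            p[f"{d}_U{g}"] = uniform_init(rng, (hidden_dim, hidden_dim))
            p[f"{d}_b{g}"] = np.zeros(hidden_dim)
    return p


def _gates(params: dict[str, np.ndarray], direction: str) -> dict[str, np.ndarray]:
    return {k: params[f"{direction}_{k}"] for k in _GATE_KEYS}


# ---------------------------------------------------------------------------
# Forward primitives
# ---------------------------------------------------------------------------

def embed_instance(
    inst: tuple[np.ndarray, np.ndarray, np.ndarray, int], params: dict[str, np.ndarray]
) -> np.ndarray:
    """Joint embeddings ``t_i = [w_i; p_i^c; p_i^d]`` as an (n, d_T + 2*d_P) array."""
    w, pc, pd, _ = inst
    if len(w) == 0:
        raise ValueError("cannot embed an instance with no tokens")
    return np.concatenate(
        [params["T"][:, w].T, params["P"][:, pc].T, params["P"][:, pd].T], axis=1
    )


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    gates: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update: logistic input/forget/output gates, tanh candidate.

    ``c_t = i ⊗ u + f ⊗ c_prev`` and ``h_t = o ⊗ tanh(c_t)``; no peephole
    terms enter the gates.
    """
    if x_t.shape[0] != gates["Wi"].shape[1] or h_prev.shape[0] != gates["Ui"].shape[1]:
        raise ValueError("lstm_step: input/state shapes do not match the gate matrices")
    i = sigmoid(gates["Wi"] @ x_t + gates["Ui"] @ h_prev + gates["bi"])
    f = sigmoid(gates["Wf"] @ x_t + gates["Uf"] @ h_prev + gates["bf"])
    o = sigmoid(gates["Wo"] @ x_t + gates["Uo"] @ h_prev + gates["bo"])
    u = np.tanh(gates["Wg"] @ x_t + gates["Ug"] @ h_prev + gates["bg"])
    c_t = i * u + f * c_prev
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def _lstm_forward(X: np.ndarray, g: dict[str, np.ndarray]) -> tuple[np.ndarray, dict]:
    """Run an LSTM left-to-right over X (n, dx); cache activations for BPTT."""
    n = X.shape[0]
    H = g["bi"].shape[0]
    hs = np.zeros((n + 1, H))
    cs = np.zeros((n + 1, H))
    cache = {k: np.zeros((n, H)) for k in ("i", "f", "o", "u", "tc")}
    for t in range(n):
        i = sigmoid(g["Wi"] @ X[t] + g["Ui"] @ hs[t] + g["bi"])
        f = sigmoid(g["Wf"] @ X[t] + g["Uf"] @ hs[t] + g["bf"])
        o = sigmoid(g["Wo"] @ X[t] + g["Uo"] @ hs[t] + g["bo"])
        u = np.tanh(g["Wg"] @ X[t] + g["Ug"] @ hs[t] + g["bg"])
        cs[t + 1] = i * u + f * cs[t]
        tc = np.tanh(cs[t + 1])
        hs[t + 1] = o * tc
        cache["i"][t], cache["f"][t], cache["o"][t], cache["u"][t], cache["tc"][t] = (
            i,
            f,
            o,
            u,
            tc,
        )
    cache["hs"], cache["cs"], cache["X"] = hs, cs, X
    return hs[1:], cache


def _lstm_backward(
    dH: np.ndarray, cache: dict, g: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backpropagate through an unrolled LSTM; returns dX and gate gradients."""
    X, hs, cs = cache["X"], cache["hs"], cache["cs"]
    n = X.shape[0]
    grads = {k: np.zeros_like(g[k]) for k in _GATE_KEYS}
    dX = np.zeros_like(X)
    dh_next = np.zeros_like(dH[0])
    dc_next = np.zeros_like(dH[0])
    for t in range(n - 1, -1, -1):
        i, f, o, u, tc = (cache[k][t] for k in ("i", "f", "o", "u", "tc"))
        dh = dH[t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * u
        du = dc * i
        df = dc * cs[t]
        dc_next = dc * f
        dai = di * i * (1.0 - i)
        daf = df * f * (1.0 - f)
        dao = do * o * (1.0 - o)
        dag = du * (1.0 - u * u)
        for name, da in (("i", dai), ("f", daf), ("o", dao), ("g", dag)):
            grads[f"W{name}"] += np.outer(da, X[t])
            grads[f"U{name}"] += np.outer(da, hs[t])
            grads[f"b{name}"] += da
        dh_next = g["Ui"].T @ dai + g["Uf"].T @ daf + g["Uo"].T @ dao + g["Ug"].T @ dag
        dX[t] = g["Wi"].T @ dai + g["Wf"].T @ daf + g["Wo"].T @ dao + g["Wg"].T @ dag
    return dX, grads


def encode_instance(
    inst: tuple[np.ndarray, np.ndarray, np.ndarray, int], params: dict[str, np.ndarray]
) -> np.ndarray:
    """Instance representation: mean over bidirectional states [h_f; h_b]."""
    X = embed_instance(inst, params)
    hf, _ = _lstm_forward(X, _gates(params, "f"))
    hb_rev, _ = _lstm_forward(X[::-1], _gates(params, "b"))
    h = np.concatenate([hf, hb_rev[::-1]], axis=1)
    return h.mean(axis=0)


def concept_embedding(
    concept_idx: int, hyponym_tag: int, params: dict[str, np.ndarray]
) -> np.ndarray:
    """Concept embedding ``c = [e; q]`` from the identifier and hyponym tables."""
    return np.concatenate([params["E"][:, concept_idx], params["Q"][:, hyponym_tag]])


def entity_difference(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Translation-style relation representation ``r = c1 - c2``."""
    if c1.shape != c2.shape:
        raise ValueError("concept embeddings must have equal dimension")
    return c1 - c2


def attention_weights(
    s_list: list[np.ndarray],
    m_list: list[np.ndarray],
    r: np.ndarray,
    params: dict[str, np.ndarray],
) -> np.ndarray:
    """Softmax attention over instances from scores v·tanh(Ws s + Wm m + Wr r + bs)."""
    if not s_list:
        raise ValueError("attention over an empty bag is undefined")
    gam = np.array(
        [
            params["v"]
            @ np.tanh(params["Ws"] @ s + params["Wm"] @ m + params["Wr"] @ r + params["bs"])
            for s, m in zip(s_list, m_list)
        ]
    )
    return softmax(gam)


# ---------------------------------------------------------------------------
# Full bag forward / backward
# ---------------------------------------------------------------------------

def _forward_bag(
    bag: BagData, params: dict[str, np.ndarray], z_mask: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Forward pass over one bag; the trace carries everything BPTT needs."""
    if not bag.insts:
        raise ValueError("empty bag")
    trace: dict = {"insts": []}
    s_list, m_list = [], []
    for inst in bag.insts:
        X = embed_instance(inst, params)
        hf, cf = _lstm_forward(X, _gates(params, "f"))
        hb_rev, cb = _lstm_forward(X[::-1], _gates(params, "b"))
        h = np.concatenate([hf, hb_rev[::-1]], axis=1)
        s = h.mean(axis=0)
        s_list.append(s)
        m_list.append(params["L"][:, inst[3]])
        trace["insts"].append({"cf": cf, "cb": cb, "n": X.shape[0]})
    c1 = concept_embedding(bag.chem_idx, bag.chem_tag, params)
    c2 = concept_embedding(bag.dis_idx, bag.dis_tag, params)
    r = entity_difference(c1, c2)

    q = [
        params["Ws"] @ s + params["Wm"] @ m + params["Wr"] @ r + params["bs"]
        for s, m in zip(s_list, m_list)
    ]
    tq = [np.tanh(x) for x in q]
    gam = np.array([params["v"] @ t for t in tq])
    alpha = softmax(gam)
    u = sum(a * s for a, s in zip(alpha, s_list))

    kvec = np.concatenate([c1, c2, u])
    z = np.tanh(params["W1"] @ kvec + params["b1"])
    zd = z * z_mask if z_mask is not None else z
    logits = params["W2"] @ zd + params["b2"]
    o = softmax(logits)

    trace.update(
        s_list=s_list,
        m_list=m_list,
        c1=c1,
        c2=c2,
        r=r,
        tq=tq,
        alpha=alpha,
        u=u,
        kvec=kvec,
        z=z,
        zd=zd,
        z_mask=z_mask,
        o=o,
    )
    return o, trace


def classify_bag(
    bag: BagData,
    params: dict[str, np.ndarray],
    train_mode: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Class distribution over {negative, positive} for one bag, with trace.

    Dropout applies to the hidden vector ``z`` only when ``train_mode`` is on.
    """
    mask = None
    if train_mode and dropout > 0.0:
        if rng is None:
            raise ValueError("train-mode dropout requires an RNG")
        mask = dropout_mask(rng, params["b1"].shape[0], dropout)
    return _forward_bag(bag, params, mask)


def _backward_bag(
    bag: BagData,
    params: dict[str, np.ndarray],
    trace: dict,
    dlogits: np.ndarray,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate dLoss/dθ for one bag into ``grads`` given dLoss/dlogits."""
    grads["W2"] += np.outer(dlogits, trace["zd"])
    grads["b2"] += dlogits
    dzd = params["W2"].T @ dlogits
    if trace["z_mask"] is not None:
        dzd = dzd * trace["z_mask"]
    z = trace["z"]
    dpre1 = dzd * (1.0 - z * z)
    grads["W1"] += np.outer(dpre1, trace["kvec"])
    grads["b1"] += dpre1
    dk = params["W1"].T @ dpre1

    cd = trace["c1"].shape[0]
    dc1 = dk[:cd].copy()
    dc2 = dk[cd : 2 * cd].copy()
    du = dk[2 * cd :]

    s_list, m_list, alpha, tq = trace["s_list"], trace["m_list"], trace["alpha"], trace["tq"]
    ds_list = [alpha[k] * du for k in range(len(s_list))]
    dalpha = np.array([du @ s_list[k] for k in range(len(s_list))])
    dgam = alpha * (dalpha - float(dalpha @ alpha))  # softmax Jacobian
    dr = np.zeros_like(trace["r"])
    for k, (s, m) in enumerate(zip(s_list, m_list)):
        grads["v"] += dgam[k] * tq[k]
        dq = dgam[k] * params["v"] * (1.0 - tq[k] * tq[k])
        grads["Ws"] += np.outer(dq, s)
        grads["Wm"] += np.outer(dq, m)
        grads["Wr"] += np.outer(dq, trace["r"])
        grads["bs"] += dq
        ds_list[k] = ds_list[k] + params["Ws"].T @ dq
        grads["L"][:, bag.insts[k][3]] += params["Wm"].T @ dq
        dr += params["Wr"].T @ dq
    dc1 += dr
    dc2 -= dr

    ident_dim = params["E"].shape[0]
    grads["E"][:, bag.chem_idx] += dc1[:ident_dim]
    grads["Q"][:, bag.chem_tag] += dc1[ident_dim:]
    grads["E"][:, bag.dis_idx] += dc2[:ident_dim]
    grads["Q"][:, bag.dis_tag] += dc2[ident_dim:]

    word_dim = params["T"].shape[0]
    pos_dim = params["P"].shape[0]
    hidden_dim = params["f_bi"].shape[0]
    for k, inst in enumerate(bag.insts):
        n = trace["insts"][k]["n"]
        ds = ds_list[k]
        dh = np.tile(ds / n, (n, 1))  # mean pooling
        dhf, dhb = dh[:, :hidden_dim], dh[:, hidden_dim:]
        dXf, gf = _lstm_backward(dhf, trace["insts"][k]["cf"], _gates(params, "f"))
        dXb_rev, gb = _lstm_backward(dhb[::-1], trace["insts"][k]["cb"], _gates(params, "b"))
        dX = dXf + dXb_rev[::-1]
        for gk in _GATE_KEYS:
            grads[f"f_{gk}"] += gf[gk]
            grads[f"b_{gk}"] += gb[gk]
        w, pc, pd, _ = inst
        for t in range(n):
            grads["T"][:, w[t]] += dX[t, :word_dim]
            grads["P"][:, pc[t]] += dX[t, word_dim : word_dim + pos_dim]
            grads["P"][:, pd[t]] += dX[t, word_dim + pos_dim :]


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def intra_loss(
    bags: list[BagData], params: dict[str, np.ndarray], l2: float = 0.0
) -> float:
    """Mean negative log likelihood of the bag labels plus λ‖θ‖² (no dropout)."""
    if not bags:
        raise ValueError("empty batch")
    total = 0.0
    for bag in bags:
        o, _ = _forward_bag(bag, params)
        total -= np.log(max(o[bag.label], LOG_FLOOR))
    return total / len(bags) + l2 * l2_norm_sq(params)


def intra_loss_and_grads(
    bags: list[BagData],
    params: dict[str, np.ndarray],
    l2: float = 0.0,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Objective value and analytic gradients for one mini-batch of bags."""
    if not bags:
        raise ValueError("empty batch")
    grads = zeros_like_params(params)
    total = 0.0
    m = len(bags)
    for bag in bags:
        o, trace = classify_bag(bag, params, train_mode=True, dropout=dropout, rng=rng)
        total -= np.log(max(o[bag.label], LOG_FLOOR))
        dlogits = o.copy()
        dlogits[bag.label] -= 1.0
        _backward_bag(bag, params, trace, dlogits / m, grads)
    loss = total / m + l2 * l2_norm_sq(params)
    if l2:
        for k, v in params.items():
            grads[k] += 2.0 * l2 * v
    return loss, grads


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class IntraAttentionClassifier(ClassifierMixin, BaseEstimator):
    """Attention-based bag classifier over intra-sentence relation bags.

    Parameters default to the production hyper-parameters (learning rate
    0.004, batch of 500 bags, 200 LSTM hidden units, 300/50/100/50/50-d word /
    position / identifier / hyponym / location embeddings, 250 hidden nodes,
    dropout 0.3); ``attention_dim`` (rows of the attention scoring matrices)
    and the L2 factor are package choices.  ``word_vectors`` may hold a
    pre-trained token -> vector map used to initialize the word table.

    After :meth:`fit`, ``params_`` holds every learned array, ``word_index_``
    and ``concept_index_`` the vocabularies, and ``loss_curve_`` the per-epoch
    training objective.
    """

    def __init__(
        self,
        learning_rate: float = 0.004,
        batch_size: int = 500,
        hidden_dim: int = 200,
        word_dim: int = 300,
        position_dim: int = 50,
        identifier_dim: int = 100,
        hyponym_dim: int = 50,
        location_dim: int = 50,
        attention_dim: int = 100,
        hidden_nodes: int = 250,
        dropout: float = 0.3,
        l2: float = 1e-4,
        max_dist: int = DEFAULT_MAX_DIST,
        n_epochs: int = 15,
        validation_fraction: float = 0.1,
        patience: int = 3,
        word_vectors: dict[str, np.ndarray] | None = None,
        random_state: int | None = 0,
    ) -> None:
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.hidden_dim = hidden_dim
        self.word_dim = word_dim
        self.position_dim = position_dim
        self.identifier_dim = identifier_dim
        self.hyponym_dim = hyponym_dim
        self.location_dim = location_dim
        self.attention_dim = attention_dim
        self.hidden_nodes = hidden_nodes
        self.dropout = dropout
        self.l2 = l2
        self.max_dist = max_dist
        self.n_epochs = n_epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.word_vectors = word_vectors
        self.random_state = random_state

    # -- encoding ----------------------------------------------------------

    def _build_vocab(self, bags: list[RelationBag]) -> None:
        words = sorted({t for b in bags for i in b.instances for t in i.tokens})
        concepts = sorted({c for b in bags for c in (b.chemical_id, b.disease_id)})
        self.word_index_ = {UNK_SYMBOL: 0}
        for w in words:
            self.word_index_.setdefault(w, len(self.word_index_))
        self.concept_index_ = {UNK_CONCEPT: 0}
        for c in concepts:
            self.concept_index_.setdefault(c, len(self.concept_index_))

    def _encode_bag(self, bag: RelationBag) -> BagData:
        wi = self.word_index_
        ci = self.concept_index_
        insts = []
        for inst in bag.instances:
            w = np.array([wi.get(t, 0) for t in inst.tokens], dtype=np.intp)
            pc = np.array(inst.pos_chem, dtype=np.intp) + self.max_dist
            pd = np.array(inst.pos_dis, dtype=np.intp) + self.max_dist
            insts.append((w, pc, pd, inst.location.value))
        return BagData(
            insts=insts,
            chem_idx=ci.get(bag.chemical_id, 0),
            chem_tag=bag.chem_hyponym,
            dis_idx=ci.get(bag.disease_id, 0),
            dis_tag=bag.dis_hyponym,
            label=bag.label,
        )

    # -- training ----------------------------------------------------------

    def fit(self, X: list[RelationBag], y=None) -> "IntraAttentionClassifier":
        bags = list(X)
        if y is not None:
            labels = np.asarray(y, dtype=int)
            if len(labels) != len(bags):
                raise ValueError("y length does not match the number of bags")
        else:
            labels = np.array([b.label for b in bags], dtype=int)
        if len(set(labels.tolist())) < 2:
            raise ValueError(
                "training requires at least one positive and one negative bag"
            )
        rng = np.random.default_rng(self.random_state)
        self._build_vocab(bags)
        self.classes_ = np.array([0, 1])
        params = init_intra_params(
            rng,
            n_words=len(self.word_index_),
            n_concepts=len(self.concept_index_),
            word_dim=self.word_dim,
            position_dim=self.position_dim,
            identifier_dim=self.identifier_dim,
            hyponym_dim=self.hyponym_dim,
            location_dim=self.location_dim,
            hidden_dim=self.hidden_dim,
            attention_dim=self.attention_dim,
            hidden_nodes=self.hidden_nodes,
            max_dist=self.max_dist,
        )
        if self.word_vectors:
            for tok, vec in self.word_vectors.items():
                j = self.word_index_.get(tok)
                if j is not None and len(vec) == self.word_dim:
                    params["T"][:, j] = vec

        data = [self._encode_bag(b) for b in bags]
        for bd, lab in zip(data, labels):
            bd.label = int(lab)

        order = rng.permutation(len(data))
        n_dev = (
            int(round(self.validation_fraction * len(data)))
            if self.validation_fraction > 0
            else 0
        )
        dev = [data[i] for i in order[:n_dev]]
        train = [data[i] for i in order[n_dev:]]
        if len({b.label for b in train}) < 2:  # tiny sets: fall back to all data
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
                loss, grads = intra_loss_and_grads(
                    batch, params, l2=self.l2, dropout=self.dropout, rng=rng
                )
                opt.step(params, grads)
                epoch_loss += loss * len(batch)
            self.loss_curve_.append(epoch_loss / len(train))
            if dev:
                dev_loss = intra_loss(dev, params, l2=0.0)
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

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: list[RelationBag]) -> np.ndarray:
        probs = np.empty((len(X), 2))
        for i, bag in enumerate(X):
            o, _ = _forward_bag(self._encode_bag(bag), self.params_)
            probs[i] = o
        return probs

    def predict(self, X: list[RelationBag]) -> np.ndarray:
        if not len(X):
            return np.zeros(0, dtype=int)
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def bag_attention(self, bag: RelationBag) -> np.ndarray:
        """Attention weights over a bag's instances under the fitted model."""
        _, trace = _forward_bag(self._encode_bag(bag), self.params_)
        return trace["alpha"]

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        import json

        meta = {
            "kind": "intra",
            "config": {
                k: v for k, v in self.get_params().items() if k != "word_vectors"
            },
            "word_index": self.word_index_,
            "concept_index": self.concept_index_,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params_)

    @classmethod
    def load(cls, path: str) -> "IntraAttentionClassifier":
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


def train_intra(bags: list[RelationBag], **config) -> IntraAttentionClassifier:
    """Fit an :class:`IntraAttentionClassifier` on labeled bags."""
    return IntraAttentionClassifier(**config).fit(bags)


def predict_intra(
    bags: list[RelationBag], model: IntraAttentionClassifier
) -> list[DocPrediction]:
    """Score bags as document-level predictions (positive iff score >= 0.5)."""
    if not bags:
        return []
    scores = model.predict_proba(bags)[:, 1]
    return [
        DocPrediction(b.doc_id, b.chemical_id, b.disease_id, float(s), "intra")
        for b, s in zip(bags, scores)
    ]
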