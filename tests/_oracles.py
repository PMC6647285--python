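"""Independent scalar-loop reference implementations.

Everything here is written with explicit Python loops over indices and
``math`` scalar functions, deliberately avoiding the vectorized code paths of
the package, so the two can serve as mutual checks.
"""

from __future__ import annotations

import math


def _sig(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))


def _matvec(W, x):
    return [sum(W[i][j] * x[j] for j in range(len(x))) for i in range(len(W))]


def _softmax(xs):
    m = max(xs)
    es = [math.exp(x - m) for x in xs]
    s = sum(es)
    return [e / s for e in es]


def lstm_sequence_scalar(X, g):
    """Hidden states of a left-to-right LSTM pass, one scalar op at a time."""
    H = len(g["bi"])
    h = [0.0] * H
    c = [0.0] * H
    out = []
    for x in X:
        i = [_sig(v + u + b) for v, u, b in zip(_matvec(g["Wi"], x), _matvec(g["Ui"], h), g["bi"])]
        f = [_sig(v + u + b) for v, u, b in zip(_matvec(g["Wf"], x), _matvec(g["Uf"], h), g["bf"])]
        o = [_sig(v + u + b) for v, u, b in zip(_matvec(g["Wo"], x), _matvec(g["Uo"], h), g["bo"])]
        u_ = [
            math.tanh(v + u + b)
            for v, u, b in zip(_matvec(g["Wg"], x), _matvec(g["Ug"], h), g["bg"])
        ]
        c = [ii * uu + ff * cc for ii, uu, ff, cc in zip(i, u_, f, c)]
        h = [oo * math.tanh(cc) for oo, cc in zip(o, c)]
        out.append(list(h))
    return out


def encode_instance_scalar(inst, params):
    """Mean-pooled bidirectional encoding of one instance (scalar reference)."""
    w, pc, pd, _ = inst
    T, P = params["T"], params["P"]
    X = [
        [T[r][w[t]] for r in range(len(T))]
        + [P[r][pc[t]] for r in range(len(P))]
        + [P[r][pd[t]] for r in range(len(P))]
        for t in range(len(w))
    ]
    gf = {k: params[f"f_{k}"].tolist() for k in ("Wi", "Ui", "bi", "Wf", "Uf", "bf", "Wo", "Uo", "bo", "Wg", "Ug", "bg")}
    gb = {k: params[f"b_{k}"].tolist() for k in ("Wi", "Ui", "bi", "Wf", "Uf", "bf", "Wo", "Uo", "bo", "Wg", "Ug", "bg")}
    hf = lstm_sequence_scalar(X, gf)
    hb = lstm_sequence_scalar(X[::-1], gb)[::-1]
    n = len(X)
    joined = [hf[t] + hb[t] for t in range(n)]
    dim = len(joined[0])
    return [sum(joined[t][r] for t in range(n)) / n for r in range(dim)]


def attention_scalar(s_list, m_list, r, params):
    """Softmax attention weights from v.tanh(Ws s + Wm m + Wr r + bs)."""
    Ws, Wm, Wr = params["Ws"].tolist(), params["Wm"].tolist(), params["Wr"].tolist()
    bs, v = params["bs"].tolist(), params["v"].tolist()
    gam = []
    for s, m in zip(s_list, m_list):
        pre = [
            a + b + c + d
            for a, b, c, d in zip(_matvec(Ws, list(s)), _matvec(Wm, list(m)), _matvec(Wr, list(r)), bs)
        ]
        gam.append(sum(vv * math.tanh(x) for vv, x in zip(v, pre)))
    return _softmax(gam)


def classify_bag_scalar(bag, params):
    """Scalar forward pass of the full bag classifier (no dropout)."""
    s_list = [encode_instance_scalar(inst, params) for inst in bag.insts]
    L = params["L"]
    m_list = [[L[r][inst[3]] for r in range(len(L))] for inst in bag.insts]
    E, Q = params["E"], params["Q"]
    c1 = [E[r][bag.chem_idx] for r in range(len(E))] + [Q[r][bag.chem_tag] for r in range(len(Q))]
    c2 = [E[r][bag.dis_idx] for r in range(len(E))] + [Q[r][bag.dis_tag] for r in range(len(Q))]
    r_vec = [a - b for a, b in zip(c1, c2)]
    alpha = attention_scalar(s_list, m_list, r_vec, params)
    dim_s = len(s_list[0])
    u = [sum(alpha[k] * s_list[k][j] for k in range(len(s_list))) for j in range(dim_s)]
    kvec = c1 + c2 + u
    W1, b1 = params["W1"].tolist(), params["b1"].tolist()
    z = [math.tanh(x + b) for x, b in zip(_matvec(W1, kvec), b1)]
    W2, b2 = params["W2"].tolist(), params["b2"].tolist()
    return _softmax([x + b for x, b in zip(_matvec(W2, z), b2)]), alpha


def autoencoder_scalar(l, params):
    """Scalar forward pass of the encoder/decoder/softmax stack (no dropout)."""
    W3, b3 = params["W3"].tolist(), params["b3"].tolist()
    a = [math.tanh(x + b) for x, b in zip(_matvec(W3, list(l)), b3)]
    W4, b4 = params["W4"].tolist(), params["b4"].tolist()
    j = [math.tanh(x + b) for x, b in zip(_matvec(W4, a), b4)]
    W5, b5 = params["W5"].tolist(), params["b5"].tolist()
    return _softmax([x + b for x, b in zip(_matvec(W5, j), b5)])


def prf_scalar(predicted, gold):
    """Brute-force precision/recall/F1 by explicit membership testing."""
    predicted = list(set(map(tuple, predicted)))
    gold = list(set(map(tuple, gold)))
    tp = sum(1 for p in predicted if p in gold)
    fp = len(predicted) - tp
    fn = sum(1 for g in gold if g not in predicted)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def hyponym_scalar(concepts, tree):
    """Exhaustive pairwise proper-prefix comparison of tree numbers."""
    tags = {}
    for c in concepts:
        tag = 1
        for other in concepts:
            if other == c:
                continue
            for tn_c in tree.get(c, []):
                for tn_o in tree.get(other, []):
                    if tn_o != tn_c and tn_o.startswith(tn_c + "."):
                        tag = 0
        tags[c] = tag
    return tags
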