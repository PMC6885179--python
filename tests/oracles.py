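"""Independent brute-force oracles, coded without numpy vectorisation.

These re-derive the quantities under test from their definitions (scalar
loops over the gate equations, exhaustive pair enumeration for AUROC) and
deliberately share no code with the package implementation.
"""

import math


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


def _dot(w_row, vec):
    return sum(wi * vi for wi, vi in zip(w_row, vec))


def lstm_step_oracle(params, x_t, h_prev, C_prev):
    """One gate update, scalar loops over plain Python lists."""
    H = len(h_prev)
    z = list(h_prev) + list(x_t)
    h_new, C_new = [], []
    for j in range(H):
        f = _sig(_dot(params["w_f"][j], z) + params["b_f"][j])
        i = _sig(_dot(params["w_i"][j], z) + params["b_i"][j])
        o = _sig(_dot(params["w_o"][j], z) + params["b_o"][j])
        g = math.tanh(_dot(params["w_c"][j], z) + params["b_c"][j])
        C = f * C_prev[j] + i * g
        h_new.append(o * math.tanh(C))
        C_new.append(C)
    return h_new, C_new


def lstm_forward_oracle(params, V):
    """Score a D×T list-of-lists instance by chaining the step oracle."""
    H = len(params["b_f"])
    T = len(V[0])
    h = [0.0] * H
    C = [0.0] * H
    for t in range(T):
        x_t = [row[t] for row in V]
        h, C = lstm_step_oracle(params, x_t, h, C)
    return _sig(_dot(params["w_ho"], h) + params["b_ho"])


def params_to_lists(p):
    """Convert an LSTMParams into the plain-list dict the oracle consumes."""
    d = p.to_dict()
    out = {k: [list(row) for row in d[k]] for k in ("w_f", "w_i", "w_o", "w_c")}
    for k in ("b_f", "b_i", "b_o", "b_c", "w_ho"):
        out[k] = list(d[k])
    out["b_ho"] = float(d["b_ho"])
    return out


def auroc_pairs_oracle(scores, labels):
    """AUROC by exhaustive positive/negative pair comparison, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
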