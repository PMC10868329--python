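"""Literal, loop-based reference evaluations of the attention layers and head.

These re-derive every update rule element by element with plain numpy
loops, reading only the layers' parameter arrays -- independent of the
vectorized implementation paths they are compared against.
"""

import math

import numpy as np


def softmax_vec(x):
    e = np.exp(x - x.max())
    return e / e.sum()


def cosine(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def nff_layer_loop(layer, reps, mask, node_types, tau):
    """Element-wise evaluation of one neighbor-fusion layer, all channels."""
    n = mask.shape[0]
    rel = layer.rel_weights.data
    posi, topo = reps["posi"], reps["topo"]
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            c[i, j] = (tau * cosine(posi[i], posi[j])
                       + (1 - tau) * cosine(topo[i], topo[j]) + 1) / 2
    out = {}
    for ch in ("simi", "posi", "topo"):
        h = reps[ch]
        head_sum = np.zeros((n, layer.embed_dim))
        for k in range(layer.n_heads):
            w_by_type = {t: layer.w_type[ch][k][t].data for t in (0, 1)}
            wp = layer.w_p[ch][k].data
            wres = layer.w_res[ch][k].data
            s = np.zeros((n, n))
            for i in range(n):
                q = softmax_vec(h[i] @ w_by_type[node_types[i]] @ wp)
                for j in range(n):
                    key = h[j] @ w_by_type[node_types[j]]
                    norm = np.linalg.norm(key)
                    s[i, j] = 0.0 if norm == 0 else q @ (key / norm)
            head_out = np.zeros((n, layer.embed_dim))
            for i in range(n):
                neighbors = np.flatnonzero(mask[i])
                psi = np.array([node_types[i] + 2 * node_types[j] for j in neighbors])
                logits = rel[psi] * s[i, neighbors] * c[i, neighbors]
                a = softmax_vec(logits)
                agg = np.zeros(layer.embed_dim)
                for a_ij, j in zip(a, neighbors):
                    agg += a_ij * (h[j] @ w_by_type[node_types[i]])
                head_out[i] = np.maximum(agg + h[i] @ wres, 0.0)
            head_sum += head_out
        out[ch] = head_sum / layer.n_heads
    return out, c


def layer_norm_loop(x, gain, bias, eps=1e-5):
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    return (x - mu) / math.sqrt(var + eps) * gain + bias


def gff_layer_loop(layer, relations, h, node_types):
    """Element-wise evaluation of one relation-aware transformer layer."""
    n = h.shape[0]
    table = relations.table.data
    dh = layer.head_dim
    heads = []
    for hd in range(layer.n_heads):
        m_head = np.zeros((n, dh))
        for i in range(n):
            logits = np.zeros(n)
            values = np.zeros((n, dh))
            for j in range(n):
                psi = node_types[i] + 2 * node_types[j]
                e = table[psi]
                q = np.concatenate([h[i], e]) @ layer.w_q[hd][node_types[i]].data
                k = np.concatenate([h[j], e]) @ layer.w_k[hd][node_types[j]].data
                values[j] = np.concatenate([h[j], e]) @ layer.w_v[hd][node_types[j]].data
                logits[j] = q @ k / math.sqrt(dh)
            f = softmax_vec(logits)
            m_head[i] = f @ values
        heads.append(m_head)
    m = np.concatenate(heads, axis=1)
    out = np.zeros_like(h[:, :layer.embed_dim])
    for i in range(n):
        n_i = layer_norm_loop(m[i] @ layer.w1.data + h[i],
                              layer.ln1_gain.data, layer.ln1_bias.data)
        out[i] = layer_norm_loop(np.maximum(n_i @ layer.w2.data, 0.0) @ layer.w3.data
                                 + n_i, layer.ln2_gain.data, layer.ln2_bias.data)
    return out


def prediction_head_loop(head, h_tilde, drug_idx, microbe_idx, n_drugs):
    """Pair probabilities via the literal concatenated affine maps."""
    w_attr = np.vstack([head.w_attr_drug.data, head.w_attr_microbe.data])
    out = np.zeros((len(drug_idx), 2))
    for row, (d, m) in enumerate(zip(drug_idx, microbe_idx)):
        pair = np.concatenate([h_tilde[d], h_tilde[n_drugs + m]])
        u = np.maximum(pair @ w_attr + head.b_attr.data, 0.0)
        out[row] = softmax_vec(u @ head.w_pred.data + head.b_pred.data)
    return out
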