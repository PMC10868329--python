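"""Whole-graph feature fusion (GFF): a relation-aware graph transformer.

Unlike the neighbor module, attention here is dense over ALL node pairs,
letting a drug attend to microbes it is not directly linked to.  Each
query/key/value projection consumes the node representation concatenated
with an embedding of the pair's relation type (a learned 4-row table,
shared across layers), and the projection weights are specific to the
node's type.  Because the relation type depends only on the (target type,
source type) pair, projections are computed blockwise -- two query
variants per target node and two key/value variants per source node --
rather than per pair.

Each layer follows the transformer recipe: scaled dot-product attention
per head, head concatenation, a residual + LayerNorm, then a rectified
feed-forward map with a second residual + LayerNorm.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .heterograph import DRUG, MICROBE
from .nff import relationship_type

__all__ = [
    "RelationEmbedding",
    "GFFLayer",
    "GFFStack",
    "qkv_projection",
    "global_attention_weights",
    "layer_norm",
]

_LN_EPS = 1e-5


class RelationEmbedding:
    """Learned embedding table for the four relation types.

    Equivalent to linearly transforming a one-hot relation code: row psi of
    the weight matrix is the embedding of relation psi.
    """

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        self.embed_dim = embed_dim
        self.table = ad.glorot_uniform(rng, 4, embed_dim)

    def parameters(self) -> list[Tensor]:
        return [self.table]

    def embed(self, psi: int) -> Tensor:
        if psi not in (0, 1, 2, 3):
            raise ValueError(f"relation code must be in 0..3, got {psi}")
        return ad.take(self.table, slice(psi, psi + 1))  # (1, embed_dim)


def qkv_projection(h_i: np.ndarray, h_j: np.ndarray, e_psi: np.ndarray,
                   w_q: np.ndarray, w_k: np.ndarray, w_v: np.ndarray):
    """Single-pair query/key/value vectors (numpy reference, row convention).

    ``q = [h_i, e_psi] W_q`` with the target node's Q weights; ``k`` and
    ``v`` use the source node's K/V weights on ``[h_j, e_psi]``.
    """
    qi = np.concatenate([np.asarray(h_i, float), np.asarray(e_psi, float)])
    kj = np.concatenate([np.asarray(h_j, float), np.asarray(e_psi, float)])
    return qi @ np.asarray(w_q), kj @ np.asarray(w_k), kj @ np.asarray(w_v)


def global_attention_weights(q: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Softmax over all nodes of scaled dot products (numpy reference)."""
    q = np.asarray(q, float)
    keys = np.asarray(keys, float)
    logits = keys @ q / math.sqrt(q.size)
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = _LN_EPS) -> Tensor:
    """Per-row layer normalization with learned affine rescale."""
    mu = ad.mean(x, axis=1, keepdims=True)
    centered = x - mu
    var = ad.mean(centered**2, axis=1, keepdims=True)
    return ad.mul(centered / ad.sqrt(var + eps), gain) + bias


class GFFLayer:
    """One relation-aware transformer layer over the multi-modal channel."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads != 0:
            raise ValueError("embed_dim must be divisible by the head count")
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        # per head, per node type: Q/K/V over the concatenated (h, e_psi) input
        self.w_q: list[dict[int, Tensor]] = []
        self.w_k: list[dict[int, Tensor]] = []
        self.w_v: list[dict[int, Tensor]] = []
        for _ in range(n_heads):
            self.w_q.append({t: ad.glorot_uniform(rng, 2 * embed_dim, self.head_dim)
                             for t in (DRUG, MICROBE)})
            self.w_k.append({t: ad.glorot_uniform(rng, 2 * embed_dim, self.head_dim)
                             for t in (DRUG, MICROBE)})
            self.w_v.append({t: ad.glorot_uniform(rng, 2 * embed_dim, self.head_dim)
                             for t in (DRUG, MICROBE)})
        self.w1 = ad.glorot_uniform(rng, embed_dim, embed_dim)
        self.w2 = ad.glorot_uniform(rng, embed_dim, embed_dim)
        self.w3 = ad.glorot_uniform(rng, embed_dim, embed_dim)
        self.ln1_gain = Tensor(np.ones(embed_dim), requires_grad=True)
        self.ln1_bias = Tensor(np.zeros(embed_dim), requires_grad=True)
        self.ln2_gain = Tensor(np.ones(embed_dim), requires_grad=True)
        self.ln2_bias = Tensor(np.zeros(embed_dim), requires_grad=True)
        self.last_attention: list[np.ndarray] = []

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for head in range(self.n_heads):
            params.extend(self.w_q[head].values())
            params.extend(self.w_k[head].values())
            params.extend(self.w_v[head].values())
        params.extend([self.w1, self.w2, self.w3,
                       self.ln1_gain, self.ln1_bias, self.ln2_gain, self.ln2_bias])
        return params

    def forward(self, h_prev: Tensor, relations: RelationEmbedding,
                n_drugs: int) -> Tensor:
        n_nodes = h_prev.shape[0]
        blocks = {DRUG: slice(0, n_drugs), MICROBE: slice(n_drugs, n_nodes)}
        scale = 1.0 / math.sqrt(self.head_dim)
        self.last_attention = []
        head_outputs = []
        for head in range(self.n_heads):
            # blockwise q/k/v: the relation embedding repeats within a block
            def project(rows: slice, own_type: int, other_type: int,
                        weight: Tensor, as_target: bool) -> Tensor:
                psi = (relationship_type(own_type, other_type) if as_target
                       else relationship_type(other_type, own_type))
                h_block = ad.take(h_prev, rows)
                count = h_block.shape[0]
                e_rows = ad.take(relations.table,
                                 np.full(count, psi, dtype=int))
                return ad.matmul(ad.concat([h_block, e_rows], axis=1), weight)

            logits_rows, value_blocks = [], {}
            for t_src in (DRUG, MICROBE):
                value_blocks[t_src] = {}
            for t_tgt in (DRUG, MICROBE):
                row_logits = []
                for t_src in (DRUG, MICROBE):
                    q = project(blocks[t_tgt], t_tgt, t_src, self.w_q[head][t_tgt],
                                as_target=True)
                    k = project(blocks[t_src], t_src, t_tgt, self.w_k[head][t_src],
                                as_target=False)
                    v = project(blocks[t_src], t_src, t_tgt, self.w_v[head][t_src],
                                as_target=False)
                    value_blocks[t_src][t_tgt] = v
                    row_logits.append(ad.mul(ad.matmul(q, ad.transpose(k)), scale))
                logits_rows.append(ad.concat(row_logits, axis=1))
            logits = ad.concat(logits_rows, axis=0)          # (N, N)
            weights = ad.softmax(logits, axis=1)
            self.last_attention.append(weights.data.copy())
            out_rows = []
            for t_tgt, rows in blocks.items():
                f_block = ad.take(weights, rows)
                agg = (ad.matmul(ad.take(f_block, (slice(None), blocks[DRUG])),
                                 value_blocks[DRUG][t_tgt])
                       + ad.matmul(ad.take(f_block, (slice(None), blocks[MICROBE])),
                                   value_blocks[MICROBE][t_tgt]))
                out_rows.append(agg)
            head_outputs.append(ad.concat(out_rows, axis=0))  # (N, head_dim)
        m = ad.concat(head_outputs, axis=1)                   # (N, embed_dim)
        n = layer_norm(ad.matmul(m, self.w1) + h_prev, self.ln1_gain, self.ln1_bias)
        out = layer_norm(ad.matmul(ad.relu(ad.matmul(n, self.w2)), self.w3) + n,
                         self.ln2_gain, self.ln2_bias)
        if not np.isfinite(out.data).all():
            raise FloatingPointError("non-finite GFF layer output (divergence)")
        return out


class GFFStack:
    """L transformer layers with a relation table shared across layers."""

    def __init__(self, embed_dim: int, n_layers: int, n_heads: int,
                 rng: np.random.Generator):
        self.relations = RelationEmbedding(embed_dim, rng)
        self.layers = [GFFLayer(embed_dim, n_heads, rng) for _ in range(n_layers)]

    def parameters(self) -> list[Tensor]:
        params = self.relations.parameters()
        for layer in self.layers:
            params.extend(layer.parameters())
        return params

    def forward(self, moda0: Tensor, n_drugs: int) -> list[Tensor]:
        reps = [moda0]
        for layer in self.layers:
            reps.append(layer.forward(reps[-1], self.relations, n_drugs))
        return reps
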