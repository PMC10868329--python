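"""Neighbor feature fusion (NFF): position/topology-sensitive graph attention.

A stack of heterogeneous graph-attention layers updates three channels in
parallel -- similarity, position and topology representations.  For a
target node i and neighbor j (neighbors = nonzero entries of the weighted
heterogeneous adjacency, always including the self-loop):

* a semantic score ``s`` is the inner product of a softmax-normalized
  "importance distribution" of the target's transformed representation
  with the L2-normalized transformed representation of the neighbor;
* a structural importance ``c in [0, 1]`` blends the cosine agreement of
  the two nodes' position and topology representations with weight
  ``tau``;
* a learned scalar ``r`` per relation type (drug<-drug, microbe<-drug,
  drug<-microbe, microbe<-microbe), initialized to 1, scales the product.

The attention weights are a softmax of ``r * s * c`` over the neighbor
set.  Each head aggregates neighbors through a target-type-specific
transform plus a per-head residual; heads are averaged and passed through
a rectifier.  All three channels share ``c`` and ``r`` but compute their
own ``s`` unless ``share_attention`` reuses the similarity channel's
attention everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .heterograph import DRUG, MICROBE

__all__ = [
    "CHANNELS",
    "ChannelRepresentations",
    "NFFLayer",
    "NFFStack",
    "relationship_type",
    "relation_type_matrix",
    "similarity_attention_score",
    "position_topology_importance",
    "fused_attention",
]

CHANNELS = ("simi", "posi", "topo")
_TYPE_CODES = {"drug": DRUG, "microbe": MICROBE, DRUG: DRUG, MICROBE: MICROBE}


def relationship_type(target_type, source_type) -> int:
    """Relation code of an edge from source j to target i.

    (drug<-drug)=0, (microbe<-drug)=1, (drug<-microbe)=2, (microbe<-microbe)=3.
    """
    try:
        t_i = _TYPE_CODES[target_type]
        t_j = _TYPE_CODES[source_type]
    except KeyError as exc:
        raise ValueError(f"unknown node type {exc.args[0]!r}") from None
    return int(t_i + 2 * t_j)


def relation_type_matrix(node_types: np.ndarray) -> np.ndarray:
    """psi[i, j] = relation code with i the target and j the source."""
    t = np.asarray(node_types, dtype=int)
    if not np.isin(t, (DRUG, MICROBE)).all():
        raise ValueError("unknown node type code")
    return t[:, None] + 2 * t[None, :]


def _safe_cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def similarity_attention_score(h_i: np.ndarray, h_j: np.ndarray,
                               w_phi_i: np.ndarray, w_phi_j: np.ndarray,
                               w_p: np.ndarray) -> float:
    """Single-pair semantic score (row-vector convention, numpy reference).

    ``softmax(h_i W_phi(i) W_p)`` dotted with ``L2norm(h_j W_phi(j))``; a
    zero key vector yields score 0.  The softmax runs over the feature
    dimension, so |score| <= 1.
    """
    q = np.asarray(h_i) @ np.asarray(w_phi_i) @ np.asarray(w_p)
    q = np.exp(q - q.max())
    q /= q.sum()
    k = np.asarray(h_j) @ np.asarray(w_phi_j)
    norm = np.linalg.norm(k)
    if norm == 0.0:
        return 0.0
    return float(q @ (k / norm))


def position_topology_importance(posi_i, posi_j, topo_i, topo_j, tau: float) -> float:
    """Structural importance c in [0, 1]: tau-weighted cosine agreement.

    ``c = [tau*cos(posi) + (1-tau)*cos(topo) + 1] / 2``; a zero-norm
    representation contributes cosine 0.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    c = (tau * _safe_cosine(np.asarray(posi_i, float), np.asarray(posi_j, float))
         + (1.0 - tau) * _safe_cosine(np.asarray(topo_i, float), np.asarray(topo_j, float))
         + 1.0) / 2.0
    return float(np.clip(c, 0.0, 1.0))


def fused_attention(scores: np.ndarray, importances: np.ndarray,
                    rel_weights: np.ndarray, rel_idx: np.ndarray,
                    neighbor_mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax of ``r * s * c`` over each neighbor set (numpy).

    Returns an (N, N) matrix whose row i sums to 1 over ``neighbor_mask[i]``
    and is 0 elsewhere; an empty neighbor set is an error.
    """
    mask = np.asarray(neighbor_mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("empty neighbor set (self-loops should prevent this)")
    logits = np.asarray(rel_weights)[np.asarray(rel_idx)] * np.asarray(scores) * np.asarray(importances)
    logits = np.where(mask, logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ChannelRepresentations:
    """Per-layer representations; index 0 holds the module inputs."""

    simi: list[Tensor] = field(default_factory=list)
    posi: list[Tensor] = field(default_factory=list)
    topo: list[Tensor] = field(default_factory=list)

    def channel(self, name: str) -> list[Tensor]:
        return getattr(self, name)

    @property
    def n_layers(self) -> int:
        return len(self.simi) - 1


class NFFLayer:
    """One attention layer updating all three channels."""

    def __init__(self, in_dims: dict[str, int], embed_dim: int, n_heads: int,
                 rng: np.random.Generator, learn_relations: bool = True):
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        # params[channel][head] = {type -> W}, Wp, Wres
        self.w_type: dict[str, list[dict[int, Tensor]]] = {}
        self.w_p: dict[str, list[Tensor]] = {}
        self.w_res: dict[str, list[Tensor]] = {}
        for ch in CHANNELS:
            d_in = in_dims[ch]
            self.w_type[ch] = [
                {t: ad.glorot_uniform(rng, d_in, embed_dim) for t in (DRUG, MICROBE)}
                for _ in range(n_heads)
            ]
            self.w_p[ch] = [ad.glorot_uniform(rng, embed_dim, embed_dim)
                            for _ in range(n_heads)]
            self.w_res[ch] = [ad.glorot_uniform(rng, d_in, embed_dim)
                              for _ in range(n_heads)]
        # relation-type importance r_psi, one scalar per relation, shared
        # across heads and channels; starts at 1
        self.rel_weights = Tensor(np.ones(4), requires_grad=learn_relations)
        self.last_attention: dict[str, list[np.ndarray]] = {}
        self.last_importance: np.ndarray | None = None

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for ch in CHANNELS:
            for head in range(self.n_heads):
                params.extend(self.w_type[ch][head].values())
                params.append(self.w_p[ch][head])
                params.append(self.w_res[ch][head])
        if self.rel_weights.requires_grad:
            params.append(self.rel_weights)
        return params

    def _typed_transform(self, h: Tensor, weights: dict[int, Tensor], n_drugs: int) -> Tensor:
        drug_part = ad.matmul(ad.take(h, slice(0, n_drugs)), weights[DRUG])
        microbe_part = ad.matmul(ad.take(h, slice(n_drugs, h.shape[0])), weights[MICROBE])
        return ad.concat([drug_part, microbe_part], axis=0)

    def _structural_importance(self, posi: Tensor, topo: Tensor, tau: float) -> Tensor:
        cos_posi = ad.matmul(ad.l2_normalize(posi, axis=1),
                             ad.transpose(ad.l2_normalize(posi, axis=1)))
        cos_topo = ad.matmul(ad.l2_normalize(topo, axis=1),
                             ad.transpose(ad.l2_normalize(topo, axis=1)))
        return (tau * cos_posi + (1.0 - tau) * cos_topo + 1.0) * 0.5

    def forward(self, reps: dict[str, Tensor], neighbor_mask: np.ndarray,
                rel_idx: np.ndarray, n_drugs: int, tau: float,
                share_attention: bool = False) -> dict[str, Tensor]:
        importance = self._structural_importance(reps["posi"], reps["topo"], tau)
        self.last_importance = importance.data.copy()
        rel_gathered = ad.take(self.rel_weights, rel_idx)
        self.last_attention = {ch: [] for ch in CHANNELS}
        new_reps: dict[str, Tensor] = {}
        shared_scores: list[Tensor] = []
        for ch in CHANNELS:
            h_prev = reps[ch]
            head_outputs = []
            for head in range(self.n_heads):
                if share_attention and ch != "simi":
                    scores = shared_scores[head]
                else:
                    transformed = self._typed_transform(h_prev, self.w_type[ch][head], n_drugs)
                    query = ad.softmax(ad.matmul(transformed, self.w_p[ch][head]), axis=1)
                    key = ad.l2_normalize(transformed, axis=1)
                    scores = ad.matmul(query, ad.transpose(key))
                    if share_attention and ch == "simi":
                        shared_scores.append(scores)
                attn = ad.masked_softmax(ad.mul(ad.mul(rel_gathered, scores), importance),
                                         neighbor_mask, axis=1)
                self.last_attention[ch].append(attn.data.copy())
                aggregated = ad.matmul(attn, h_prev)
                aggregated = self._typed_transform(aggregated, self.w_type[ch][head], n_drugs)
                residual = ad.matmul(h_prev, self.w_res[ch][head])
                head_outputs.append(ad.relu(aggregated + residual))
            total = head_outputs[0]
            for extra in head_outputs[1:]:
                total = total + extra
            out = ad.mul(total, 1.0 / self.n_heads)
            if not np.isfinite(out.data).all():
                raise FloatingPointError("non-finite NFF layer output (divergence)")
            new_reps[ch] = out
        return new_reps


class NFFStack:
    """L stacked NFF layers over the three channels."""

    def __init__(self, embed_dim: int, n_nodes: int, walk_steps: int,
                 n_layers: int, n_heads: int, rng: np.random.Generator,
                 tau: float = 0.4, learn_relations: bool = True,
                 share_attention: bool = False):
        self.tau = tau
        self.share_attention = share_attention
        first_dims = {"simi": embed_dim, "posi": n_nodes, "topo": walk_steps}
        later_dims = {ch: embed_dim for ch in CHANNELS}
        self.layers = [
            NFFLayer(first_dims if i == 0 else later_dims, embed_dim, n_heads,
                     rng, learn_relations=learn_relations)
            for i in range(n_layers)
        ]

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, simi0: Tensor, posi0: Tensor, topo0: Tensor,
                neighbor_mask: np.ndarray, rel_idx: np.ndarray,
                n_drugs: int) -> ChannelRepresentations:
        reps = {"simi": simi0, "posi": posi0, "topo": topo0}
        out = ChannelRepresentations(simi=[simi0], posi=[posi0], topo=[topo0])
        for layer in self.layers:
            reps = layer.forward(reps, neighbor_mask, rel_idx, n_drugs,
                                 self.tau, self.share_attention)
            out.simi.append(reps["simi"])
            out.posi.append(reps["posi"])
            out.topo.append(reps["topo"])
        return out
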