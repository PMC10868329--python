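"""Embedding enhancement (ES): node-type-specific supervised autoencoders.

The raw similarity and multi-modal feature rows are high-dimensional and
sparse.  Each feature family is compressed to ``embed_dim`` dimensions by
an autoencoder whose encoder/decoder parameters are specific to the node
type (drug vs microbe), and a small linear classifier on the bottleneck
predicts the node type.  The reconstruction (mean squared error) and
classification (cross-entropy) losses together sharpen the separation
between drug and microbe embedding distributions; they enter the joint
objective weighted by ``epsilon``.

With ``disable_es`` the autoencoder collapses to a single per-type linear
projection and both ES losses are dropped (zero).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .heterograph import DRUG, MICROBE

__all__ = [
    "AutoencoderStack",
    "EmbeddingEnhancer",
    "EnhancedEmbeddings",
    "reconstruction_loss",
    "classification_loss",
    "enhancement_loss",
    "one_hot_node_types",
]

_NODE_TYPES = (DRUG, MICROBE)


def one_hot_node_types(node_types: np.ndarray) -> np.ndarray:
    """One-hot labels, class order (drug, microbe)."""
    node_types = np.asarray(node_types)
    if not np.isin(node_types, _NODE_TYPES).all():
        raise ValueError("unknown node type code")
    labels = np.zeros((node_types.size, 2))
    labels[np.arange(node_types.size), node_types.astype(int)] = 1.0
    return labels


def _layer_dims(in_dim: int, embed_dim: int, n_layers: int) -> list[int]:
    # taper: in_dim -> 2*embed_dim -> ... -> embed_dim
    if n_layers == 1:
        return [in_dim, embed_dim]
    return [in_dim] + [2 * embed_dim] * (n_layers - 1) + [embed_dim]


class AutoencoderStack:
    """Encoder + decoder + node-type classifier for one feature family.

    Every affine layer exists once per node type; rows are routed through
    the parameter set selected by their type, so two nodes of the same
    type with identical features map to identical embeddings.
    """

    def __init__(self, in_dim: int, embed_dim: int, feature_family: str,
                 rng: np.random.Generator, enc_layers: int = 2, dec_layers: int = 2,
                 linear_only: bool = False):
        if feature_family not in ("simi", "moda"):
            raise ValueError(f"unknown feature family {feature_family!r}")
        self.in_dim = in_dim
        self.embed_dim = embed_dim
        self.feature_family = feature_family
        self.linear_only = linear_only
        enc_dims = [in_dim, embed_dim] if linear_only else _layer_dims(in_dim, embed_dim, enc_layers)
        dec_dims = list(reversed(enc_dims))
        self.encoder: dict[int, list[tuple[Tensor, Tensor]]] = {}
        self.decoder: dict[int, list[tuple[Tensor, Tensor]]] = {}
        for t in _NODE_TYPES:
            self.encoder[t] = [
                (ad.glorot_uniform(rng, d_in, d_out),
                 Tensor(np.zeros(d_out), requires_grad=True))
                for d_in, d_out in zip(enc_dims[:-1], enc_dims[1:])
            ]
            self.decoder[t] = [] if linear_only else [
                (ad.glorot_uniform(rng, d_in, d_out),
                 Tensor(np.zeros(d_out), requires_grad=True))
                for d_in, d_out in zip(dec_dims[:-1], dec_dims[1:])
            ]
        self.classifier_w = ad.glorot_uniform(rng, embed_dim, 2)
        self.classifier_b = Tensor(np.zeros(2), requires_grad=True)

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for t in _NODE_TYPES:
            for w, b in self.encoder[t] + self.decoder[t]:
                params.extend([w, b])
        if not self.linear_only:
            params.extend([self.classifier_w, self.classifier_b])
        return params

    # -- forward passes ------------------------------------------------------
    def _route(self, x: Tensor, node_types: np.ndarray,
               layers_by_type: dict[int, list[tuple[Tensor, Tensor]]]) -> Tensor:
        node_types = np.asarray(node_types)
        if not np.isin(node_types, _NODE_TYPES).all():
            raise ValueError("unknown node type code")
        pieces, order = [], []
        for t in _NODE_TYPES:
            idx = np.flatnonzero(node_types == t)
            if idx.size == 0:
                continue
            h = ad.take(x, idx)
            for w, b in layers_by_type[t]:
                h = ad.relu(ad.matmul(h, w) + b)
            pieces.append(h)
            order.append(idx)
        stacked = ad.concat(pieces, axis=0) if len(pieces) > 1 else pieces[0]
        perm = np.concatenate(order)
        inverse = np.empty_like(perm)
        inverse[perm] = np.arange(perm.size)
        return ad.take(stacked, inverse)

    def encode(self, features, node_types: np.ndarray) -> Tensor:
        """Project feature rows to the bottleneck via type-specific layers."""
        x = ad.as_tensor(features)
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} input features, got {x.shape[1]}")
        return self._route(x, node_types, self.encoder)

    def decode(self, embedding, node_types: np.ndarray) -> Tensor:
        if self.linear_only:
            raise ValueError("linear-only projection has no decoder")
        x = ad.as_tensor(embedding)
        if x.shape[1] != self.embed_dim:
            raise ValueError(f"expected {self.embed_dim}-dim embedding, got {x.shape[1]}")
        return self._route(x, node_types, self.decoder)

    def classify_log_probs(self, embedding) -> Tensor:
        logits = ad.matmul(ad.as_tensor(embedding), self.classifier_w) + self.classifier_b
        return ad.log_softmax(logits, axis=1)


def reconstruction_loss(features, reconstruction, batch_index) -> Tensor:
    """Mean over the batch of squared reconstruction error per row."""
    batch_index = np.asarray(batch_index)
    if batch_index.size == 0:
        raise ValueError("empty batch")
    diff = ad.take(ad.as_tensor(features), batch_index) - ad.take(
        ad.as_tensor(reconstruction), batch_index)
    return ad.mean(ad.total_sum(diff**2, axis=1))


def classification_loss(embedding, labels: np.ndarray, stack: AutoencoderStack,
                        batch_index) -> Tensor:
    """Cross-entropy of the node-type classifier over the batch.

    The classifier's affine output is normalized with a (log-)softmax so
    the cross-entropy is taken on genuine probabilities.
    """
    batch_index = np.asarray(batch_index)
    if batch_index.size == 0:
        raise ValueError("empty batch")
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim != 2 or labels.shape[1] != 2 or not (
            np.isin(labels, (0.0, 1.0)).all() and np.allclose(labels.sum(axis=1), 1.0)):
        raise ValueError("labels must be one-hot over 2 classes")
    log_probs = stack.classify_log_probs(ad.take(ad.as_tensor(embedding), batch_index))
    picked = ad.total_sum(ad.mul(log_probs, labels[batch_index]), axis=1)
    return -ad.mean(picked)


class EnhancedEmbeddings:
    """Bottleneck embeddings for both families plus the four ES losses."""

    def __init__(self, simi_emb: Tensor, moda_emb: Tensor,
                 reco_simi: Tensor, reco_moda: Tensor,
                 inty_simi: Tensor, inty_moda: Tensor):
        self.simi_emb = simi_emb
        self.moda_emb = moda_emb
        self.reco_simi = reco_simi
        self.reco_moda = reco_moda
        self.inty_simi = inty_simi
        self.inty_moda = inty_moda

    @property
    def losses(self) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        return (self.reco_simi, self.reco_moda, self.inty_simi, self.inty_moda)


def enhancement_loss(enhanced: EnhancedEmbeddings) -> Tensor:
    """Total ES loss: sum of both reconstruction and both classification terms."""
    reco_simi, reco_moda, inty_simi, inty_moda = enhanced.losses
    return reco_simi + reco_moda + inty_simi + inty_moda


class EmbeddingEnhancer:
    """The ES stage: one autoencoder stack per feature family."""

    def __init__(self, simi_dim: int, moda_dim: int, embed_dim: int,
                 rng: np.random.Generator, enc_layers: int = 2, dec_layers: int = 2,
                 disable_es: bool = False):
        self.disable_es = disable_es
        self.simi_stack = AutoencoderStack(simi_dim, embed_dim, "simi", rng,
                                           enc_layers, dec_layers, linear_only=disable_es)
        self.moda_stack = AutoencoderStack(moda_dim, embed_dim, "moda", rng,
                                           enc_layers, dec_layers, linear_only=disable_es)

    def parameters(self) -> list[Tensor]:
        return self.simi_stack.parameters() + self.moda_stack.parameters()

    def forward(self, h_simi, h_moda, node_types: np.ndarray,
                batch_index: np.ndarray | None = None) -> EnhancedEmbeddings:
        node_types = np.asarray(node_types)
        if batch_index is None:
            batch_index = np.arange(node_types.size)
        simi_emb = self.simi_stack.encode(h_simi, node_types)
        moda_emb = self.moda_stack.encode(h_moda, node_types)
        if self.disable_es:
            zero = Tensor(0.0)
            return EnhancedEmbeddings(simi_emb, moda_emb, zero, zero, zero, zero)
        labels = one_hot_node_types(node_types)
        return EnhancedEmbeddings(
            simi_emb, moda_emb,
            reconstruction_loss(h_simi, self.simi_stack.decode(simi_emb, node_types), batch_index),
            reconstruction_loss(h_moda, self.moda_stack.decode(moda_emb, node_types), batch_index),
            classification_loss(simi_emb, labels, self.simi_stack, batch_index),
            classification_loss(moda_emb, labels, self.moda_stack, batch_index),
        )

    def fit(self, h_simi, h_moda, node_types: np.ndarray, epochs: int = 50,
            lr: float = 1e-3) -> list[float]:
        """Train the stacks alone on their ES loss; returns the loss trace."""
        opt = ad.Adam(self.parameters(), lr=lr)
        trace = []
        for _ in range(epochs):
            enhanced = self.forward(h_simi, h_moda, node_types)
            loss = enhancement_loss(enhanced)
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(loss.item())
        return trace

    def classification_accuracy(self, h_simi, node_types: np.ndarray) -> float:
        """Node-type accuracy read off the similarity-family bottleneck."""
        emb = self.simi_stack.encode(h_simi, node_types)
        log_probs = self.simi_stack.classify_log_probs(emb)
        predicted = log_probs.data.argmax(axis=1)
        return float((predicted == np.asarray(node_types)).mean())
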