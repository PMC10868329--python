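"""Representation integration, pair scoring head and the joint objective.

Every node's final vector concatenates its original similarity row, all
neighbor-fusion layer outputs (position, topology, similarity channels,
layer 0 included), its original multi-modal row, and all graph-fusion
layer outputs.  A drug/microbe pair is scored by a rectified affine map on
the concatenated pair vector followed by an affine map to two logits and a
softmax, giving (unassociated, associated) probabilities that sum to 1.

The pair head is evaluated in split form -- ``h_drug @ W_top + h_microbe
@ W_bot`` -- which is algebraically the concatenated affine map without
materializing per-pair concatenations.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nff import ChannelRepresentations

__all__ = [
    "PredictionHead",
    "integrate_representations",
    "predict_pairs",
    "prediction_loss",
    "total_loss",
]


def integrate_representations(h_simi_orig: Tensor, nff_reps: ChannelRepresentations,
                              h_moda_orig: Tensor, gff_reps: list[Tensor]) -> Tensor:
    """Concatenate original features and every layer's representations.

    Order per node: [similarity row, (posi_l, topo_l, simi_l) for l = 0..L,
    multi-modal row, moda_l for l = 0..L].
    """
    if not nff_reps.simi or not gff_reps:
        raise ValueError("missing layer representations")
    pieces: list[Tensor] = [h_simi_orig]
    for posi_l, topo_l, simi_l in zip(nff_reps.posi, nff_reps.topo, nff_reps.simi):
        pieces.extend([posi_l, topo_l, simi_l])
    pieces.append(h_moda_orig)
    pieces.extend(gff_reps)
    return ad.concat(pieces, axis=1)


class PredictionHead:
    """Two affine maps with a rectifier in between, softmax on top."""

    def __init__(self, node_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.node_dim = node_dim
        self.hidden_dim = hidden_dim
        # W_attr on the concatenated pair vector, stored in split form
        self.w_attr_drug = ad.glorot_uniform(rng, 2 * node_dim, hidden_dim,
                                             shape=(node_dim, hidden_dim))
        self.w_attr_microbe = ad.glorot_uniform(rng, 2 * node_dim, hidden_dim,
                                                shape=(node_dim, hidden_dim))
        self.b_attr = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.w_pred = ad.glorot_uniform(rng, hidden_dim, 2)
        self.b_pred = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.w_attr_drug, self.w_attr_microbe, self.b_attr,
                self.w_pred, self.b_pred]

    def logits(self, h_tilde: Tensor, drug_idx: np.ndarray,
               microbe_idx: np.ndarray, n_drugs: int) -> Tensor:
        """Pair logits for (drug_idx[i], microbe_idx[i]) pairs.

        ``microbe_idx`` holds microbe-local indices; the global row is
        ``n_drugs + microbe_idx``.
        """
        if not np.isfinite(h_tilde.data).all():
            raise FloatingPointError("non-finite node representations")
        drug_idx = np.asarray(drug_idx, dtype=int)
        microbe_idx = np.asarray(microbe_idx, dtype=int)
        drug_proj = ad.matmul(ad.take(h_tilde, slice(0, n_drugs)), self.w_attr_drug)
        microbe_proj = ad.matmul(ad.take(h_tilde, slice(n_drugs, h_tilde.shape[0])),
                                 self.w_attr_microbe)
        u = ad.relu(ad.take(drug_proj, drug_idx) + ad.take(microbe_proj, microbe_idx)
                    + self.b_attr)
        return ad.matmul(u, self.w_pred) + self.b_pred


def predict_pairs(head: PredictionHead, h_tilde: Tensor, drug_idx: np.ndarray,
                  microbe_idx: np.ndarray, n_drugs: int) -> Tensor:
    """(B, 2) probabilities (unassociated, associated); rows sum to 1."""
    return ad.softmax(head.logits(h_tilde, drug_idx, microbe_idx, n_drugs), axis=1)


def prediction_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean two-class cross-entropy over the batch of pairs.

    ``labels`` is a vector of 0/1 association labels or a one-hot matrix.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty pair batch")
    if labels.ndim == 1:
        one_hot = np.zeros((labels.size, 2))
        one_hot[np.arange(labels.size), labels.astype(int)] = 1.0
        labels = one_hot
    log_probs = ad.log_softmax(logits, axis=1)
    return -ad.mean(ad.total_sum(ad.mul(log_probs, labels), axis=1))


def total_loss(gamma_proc: Tensor | float, gamma_pred: Tensor | float,
               epsilon: float) -> Tensor:
    """Joint objective: epsilon * ES loss + (1 - epsilon) * prediction loss."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    return ad.as_tensor(gamma_proc) * epsilon + ad.as_tensor(gamma_pred) * (1.0 - epsilon)
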