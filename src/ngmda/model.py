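"""The association-prediction model and its fitted results.

``NGMDAModel`` bundles a binary drug-microbe association matrix with a
drug similarity matrix and either a microbe similarity matrix or a
microbe attribute matrix (from which the cosine-similarity map is
applied).  ``fit()`` runs the full evaluation protocol -- 5-fold
cross-validation with leakage-safe graph masking, balanced negative
sampling for training and exhaustive negatives for testing -- training
one joint network per fold on the weighted sum of the embedding
enhancement loss and the pair prediction loss, and returns an
``NGMDAResults`` with per-fold metric reports, score matrices, loss
traces and a ``summary()`` table.  ``fit_full()`` trains on every known
association for prospective candidate ranking.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; with one BLAS thread two identical runs
produce bit-identical scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .config import RunConfig
from .embed_enhance import EmbeddingEnhancer, enhancement_loss
from .evaluation import (FoldSplit, MetricReport, evaluate_fold, make_cv_folds,
                         mask_training_graph)
from .gff import GFFStack
from .heterograph import (AssociationMatrix, HeteroGraphData, SimilarityMatrix,
                          build_hetero_graph_data, microbe_cosine_similarity)
from .nff import ChannelRepresentations, NFFStack, relation_type_matrix
from .predictor import (PredictionHead, integrate_representations,
                        prediction_loss, total_loss)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

__all__ = ["NGMDAModel", "NGMDAResults"]

logger = logging.getLogger("ngmda")


class _JointNetwork:
    """All trainable components for one training graph."""

    def __init__(self, graph: HeteroGraphData, cfg: RunConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.graph = graph
        n = graph.n_nodes
        np_dim = cfg.embed_dim
        self.enhancer = EmbeddingEnhancer(
            simi_dim=n, moda_dim=n, embed_dim=np_dim, rng=rng,
            enc_layers=cfg.enc_layers, dec_layers=cfg.dec_layers,
            disable_es=cfg.disable_es)
        self.nff = None if cfg.disable_nff else NFFStack(
            embed_dim=np_dim, n_nodes=n, walk_steps=graph.h_topo.shape[1],
            n_layers=cfg.nff_layers, n_heads=cfg.nff_heads, rng=rng,
            tau=cfg.effective_tau, learn_relations=not cfg.disable_rel,
            share_attention=cfg.share_channel_attention)
        self.gff = None if cfg.disable_gff else GFFStack(
            embed_dim=np_dim, n_layers=cfg.gff_layers, n_heads=cfg.gff_heads,
            rng=rng)
        nff_layers = 0 if cfg.disable_nff else cfg.nff_layers
        gff_layers = 0 if cfg.disable_gff else cfg.gff_layers
        t = graph.h_topo.shape[1]
        node_dim = (n                                   # original similarity row
                    + (n + t + np_dim)                  # layer-0 posi/topo/simi
                    + nff_layers * 3 * np_dim           # deeper NFF layers
                    + n                                 # original multi-modal row
                    + (gff_layers + 1) * np_dim)        # GFF layers incl. input
        self.head = PredictionHead(node_dim, cfg.head_dim, rng)
        # frozen constants of the computation graph
        self.c_simi = Tensor(graph.h_simi)
        self.c_moda = Tensor(graph.h_moda)
        self.c_posi = Tensor(graph.h_posi)
        self.c_topo = Tensor(graph.h_topo)
        self.neighbor_mask = graph.adjacency > 0
        self.rel_idx = relation_type_matrix(graph.node_types)

    def parameters(self) -> list[Tensor]:
        params = self.enhancer.parameters() + self.head.parameters()
        if self.nff is not None:
            params += self.nff.parameters()
        if self.gff is not None:
            params += self.gff.parameters()
        return params

    def forward(self):
        graph = self.graph
        enhanced = self.enhancer.forward(self.c_simi, self.c_moda, graph.node_types)
        if self.nff is None:
            nff_reps = ChannelRepresentations(
                simi=[enhanced.simi_emb], posi=[self.c_posi], topo=[self.c_topo])
        else:
            nff_reps = self.nff.forward(enhanced.simi_emb, self.c_posi, self.c_topo,
                                        self.neighbor_mask, self.rel_idx,
                                        graph.n_drugs)
        if self.gff is None:
            gff_reps = [enhanced.moda_emb]
        else:
            gff_reps = self.gff.forward(enhanced.moda_emb, graph.n_drugs)
        h_tilde = integrate_representations(self.c_simi, nff_reps,
                                            self.c_moda, gff_reps)
        return enhanced, nff_reps, gff_reps, h_tilde

    def score_all_pairs(self, h_tilde: Tensor) -> np.ndarray:
        """(n_drugs, n_microbes) association probabilities."""
        n_d = self.graph.n_drugs
        n_m = self.graph.n_nodes - n_d
        drug_idx = np.repeat(np.arange(n_d), n_m)
        microbe_idx = np.tile(np.arange(n_m), n_d)
        logits = self.head.logits(h_tilde, drug_idx, microbe_idx, n_d)
        shifted = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs[:, 1].reshape(n_d, n_m)


def _train_network(net: _JointNetwork, train_pairs: np.ndarray,
                   train_labels: np.ndarray, cfg: RunConfig,
                   tag: str) -> tuple[np.ndarray, list[dict]]:
    """Adam training loop; returns final score matrix and loss trace."""
    opt = ad.Adam(net.parameters(), lr=cfg.lr)
    trace: list[dict] = []
    drug_idx = train_pairs[:, 0]
    microbe_idx = train_pairs[:, 1]
    for epoch in range(cfg.epochs):
        enhanced, _, _, h_tilde = net.forward()
        logits = net.head.logits(h_tilde, drug_idx, microbe_idx, net.graph.n_drugs)
        gamma_pred = prediction_loss(logits, train_labels)
        gamma_proc = enhancement_loss(enhanced)
        loss = total_loss(gamma_proc, gamma_pred, cfg.epsilon)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"{tag}: loss diverged at epoch {epoch + 1}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        record = {
            "epoch": epoch + 1,
            "reco_simi": enhanced.reco_simi.item() if enhanced.reco_simi.size else 0.0,
            "reco_moda": enhanced.reco_moda.item() if enhanced.reco_moda.size else 0.0,
            "inty_simi": enhanced.inty_simi.item() if enhanced.inty_simi.size else 0.0,
            "inty_moda": enhanced.inty_moda.item() if enhanced.inty_moda.size else 0.0,
            "pred": gamma_pred.item(),
            "total": loss.item(),
        }
        trace.append(record)
        if epoch == 0 or (epoch + 1) % 25 == 0:
            logger.info("%s epoch %d: total=%.4f pred=%.4f", tag, epoch + 1,
                        record["total"], record["pred"])
    _, _, _, h_tilde = net.forward()
    return net.score_all_pairs(h_tilde), trace


class NGMDAResults:
    """Fitted cross-validation results: metrics, scores and diagnostics."""

    def __init__(self, model: "NGMDAModel", folds: list[FoldSplit],
                 fold_reports: list[MetricReport], fold_scores: list[np.ndarray],
                 loss_traces: list[list[dict]], seed: int):
        self.model = model
        self.folds = folds
        self.fold_reports = fold_reports
        self.fold_scores = fold_scores
        self.loss_traces = loss_traces
        self.seed = seed
        self.config = model.config

    # fold means averaged into the final figure
    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.mean_auc for r in self.fold_reports]))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean([r.mean_aupr for r in self.fold_reports]))

    @property
    def topk_recall(self) -> dict[int, float]:
        keys = self.fold_reports[0].topk_recall.keys()
        return {k: float(np.mean([r.topk_recall[k] for r in self.fold_reports]))
                for k in keys}

    def per_drug_table(self) -> pd.DataFrame:
        rows = []
        for report in self.fold_reports:
            for drug, auc, aupr in zip(report.drug_indices,
                                       report.per_drug_auc, report.per_drug_aupr):
                rows.append((report.fold_id, self.model.assoc.drug_ids[drug],
                             auc, aupr))
        return pd.DataFrame(rows, columns=["fold", "drug_id", "auc", "aupr"])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "topk_recall": {str(k): v for k, v in self.topk_recall.items()},
            "folds": [r.to_dict() for r in self.fold_reports],
        }

    def summary(self) -> str:
        lines = [
            "Microbe-drug association prediction: 5-fold cross-validation",
            "=" * 62,
            f"drugs: {self.model.assoc.n_drugs}   microbes: "
            f"{self.model.assoc.n_microbes}   known associations: "
            f"{int(self.model.assoc.values.sum())}",
            f"seed: {self.seed}   epochs/fold: {self.config.epochs}   "
            f"embed dim: {self.config.embed_dim}",
            "-" * 62,
            f"{'fold':>4} {'mean AUC':>10} {'mean AUPR':>10} "
            f"{'drugs eval.':>12} {'skipped':>8}",
        ]
        for report in self.fold_reports:
            lines.append(f"{report.fold_id:>4} {report.mean_auc:>10.4f} "
                         f"{report.mean_aupr:>10.4f} "
                         f"{report.n_drugs_evaluated:>12} "
                         f"{report.n_drugs_skipped:>8}")
        lines.append("-" * 62)
        lines.append(f"{'all':>4} {self.mean_auc:>10.4f} {self.mean_aupr:>10.4f}")
        recall = "   ".join(f"top-{k}: {v:.3f}" for k, v in
                            sorted(self.topk_recall.items()))
        lines.append(f"recall  {recall}")
        return "\n".join(lines)

    def plot_topk_recall(self, ax=None):
        """Recall-vs-k curve averaged over folds (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = sorted(self.topk_recall)
        ax.plot(ks, [self.topk_recall[k] for k in ks], marker="o")
        ax.set_xlabel("k")
        ax.set_ylabel("mean top-k recall")
        ax.set_ylim(0, 1.02)
        return ax


class NGMDAModel:
    """Heterogeneous-graph link-prediction model for drug-microbe pairs."""

    def __init__(self, assoc: AssociationMatrix, drug_sim: SimilarityMatrix,
                 microbe_sim: SimilarityMatrix | None = None,
                 microbe_attributes: np.ndarray | None = None,
                 config: RunConfig | None = None):
        if microbe_sim is None:
            if microbe_attributes is None:
                raise ValueError("provide microbe_sim or microbe_attributes")
            microbe_sim = microbe_cosine_similarity(
                microbe_attributes, assoc.microbe_ids)
        if drug_sim.values.shape[0] != assoc.n_drugs:
            raise ValueError("drug similarity does not match association matrix")
        if microbe_sim.values.shape[0] != assoc.n_microbes:
            raise ValueError("microbe similarity does not match association matrix")
        self.assoc = assoc
        self.drug_sim = drug_sim
        self.microbe_sim = microbe_sim
        self.config = config or RunConfig()

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_dataframes(cls, associations: pd.DataFrame, drug_sim: pd.DataFrame,
                        microbe_sim: pd.DataFrame | None = None,
                        microbe_attributes: pd.DataFrame | None = None,
                        config: RunConfig | None = None) -> "NGMDAModel":
        assoc = AssociationMatrix(associations.to_numpy(),
                                  list(associations.index),
                                  list(associations.columns))
        k_drug = SimilarityMatrix(drug_sim.to_numpy(), "drug",
                                  ids=list(drug_sim.index))
        k_micr = (SimilarityMatrix(microbe_sim.to_numpy(), "microbe",
                                   ids=list(microbe_sim.index))
                  if microbe_sim is not None else None)
        attrs = (microbe_attributes.to_numpy()
                 if microbe_attributes is not None else None)
        return cls(assoc, k_drug, k_micr, attrs, config)

    @classmethod
    def from_synthetic(cls, synthetic: SyntheticConfig | SyntheticDataset,
                       config: RunConfig | None = None) -> "NGMDAModel":
        dataset = (generate_dataset(synthetic)
                   if isinstance(synthetic, SyntheticConfig) else synthetic)
        return cls(dataset.assoc, dataset.drug_sim, dataset.microbe_sim,
                   config=config)

    # -- fitting -------------------------------------------------------------
    def _build_graph(self, assoc: AssociationMatrix) -> HeteroGraphData:
        cfg = self.config
        return build_hetero_graph_data(assoc, self.drug_sim, self.microbe_sim,
                                       beta=cfg.beta, walk_steps=cfg.walk_steps,
                                       binarize=cfg.binarize_adjacency)

    def fit(self, seed: int | None = None, n_folds: int = 5) -> NGMDAResults:
        """Cross-validated training and evaluation; one network per fold."""
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        folds = make_cv_folds(self.assoc, seed, n_folds=n_folds)
        reports, score_matrices, traces = [], [], []
        for fold in folds:
            masked = mask_training_graph(self.assoc, fold)
            graph = self._build_graph(masked)
            rng = np.random.default_rng(np.random.SeedSequence([seed, fold.fold_id]))
            net = _JointNetwork(graph, cfg, rng)
            pairs = np.vstack([fold.train_pos, fold.train_neg])
            labels = np.concatenate([np.ones(len(fold.train_pos), dtype=int),
                                     np.zeros(len(fold.train_neg), dtype=int)])
            scores, trace = _train_network(net, pairs, labels, cfg,
                                           tag=f"fold {fold.fold_id}")
            report = evaluate_fold(scores, fold, config=cfg.to_dict())
            logger.info("fold %d: mean AUC %.4f, mean AUPR %.4f",
                        fold.fold_id, report.mean_auc, report.mean_aupr)
            reports.append(report)
            score_matrices.append(scores)
            traces.append(trace)
        return NGMDAResults(self, folds, reports, score_matrices, traces, seed)

    def fit_full(self, seed: int | None = None) -> np.ndarray:
        """Train on all known associations; return the full score matrix.

        Used for prospective candidate ranking, mirroring the case-study
        protocol: all positives plus an equal number of sampled negatives.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        positives = self.assoc.positive_pairs()
        unobserved = np.argwhere(self.assoc.values == 0)
        chosen = rng.choice(unobserved.shape[0], size=min(len(positives),
                                                          len(unobserved)),
                            replace=False)
        pairs = np.vstack([positives, unobserved[chosen]])
        labels = np.concatenate([np.ones(len(positives), dtype=int),
                                 np.zeros(len(chosen), dtype=int)])
        graph = self._build_graph(self.assoc)
        net = _JointNetwork(graph, cfg, rng)
        scores, _ = _train_network(net, pairs, labels, cfg, tag="full")
        return scores
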