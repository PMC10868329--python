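"""Cross-validation protocol and ranking metrics.

Known associations are the positives; they are shuffled and split into
five near-equal parts.  Per fold, as many training negatives as training
positives are sampled uniformly without replacement from the unobserved
pairs; ALL remaining unobserved pairs are test negatives, so the test
class imbalance of the real screening problem is preserved.  Test
positives are masked out of the training graph to prevent label leakage.

Metrics are computed per drug over that drug's held-out candidates only
(AUC with mean-rank tie handling, step-wise AUPR/average precision,
top-k recall), then averaged over the drugs that have at least one test
positive; fold means are averaged into the final figure.  A paired
Wilcoxon signed-rank test compares two methods' per-drug metric vectors
(exact null distribution up to n = 25 after dropping zero differences,
normal approximation with continuity correction above).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .heterograph import AssociationMatrix

__all__ = [
    "FoldSplit",
    "MetricReport",
    "make_cv_folds",
    "mask_training_graph",
    "per_drug_auc_aupr",
    "topk_recall",
    "paired_wilcoxon",
    "evaluate_fold",
]

N_FOLDS = 5


@dataclass
class FoldSplit:
    """Train/test positive and negative pair sets for one fold.

    Pairs are (drug_index, microbe_index) arrays of shape (n, 2).
    """

    fold_id: int
    seed: int
    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray

    def test_pairs_of_drug(self, drug: int) -> tuple[np.ndarray, np.ndarray]:
        """(positive microbe indices, negative microbe indices) held out for a drug."""
        pos = self.test_pos[self.test_pos[:, 0] == drug, 1]
        neg = self.test_neg[self.test_neg[:, 0] == drug, 1]
        return pos, neg


@dataclass
class MetricReport:
    """Per-drug and averaged ranking metrics for one fold."""

    fold_id: int
    drug_indices: np.ndarray
    per_drug_auc: np.ndarray
    per_drug_aupr: np.ndarray
    mean_auc: float
    mean_aupr: float
    topk_recall: dict[int, float]
    n_drugs_evaluated: int
    n_drugs_skipped: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "topk_recall": {str(k): v for k, v in self.topk_recall.items()},
            "n_drugs_evaluated": self.n_drugs_evaluated,
            "n_drugs_skipped": self.n_drugs_skipped,
            "per_drug": {
                str(d): {"auc": float(a), "aupr": float(p)}
                for d, a, p in zip(self.drug_indices.tolist(),
                                   self.per_drug_auc.tolist(),
                                   self.per_drug_aupr.tolist())
            },
            "config": self.config,
        }


def make_cv_folds(b: AssociationMatrix, seed: int,
                  n_folds: int = N_FOLDS) -> list[FoldSplit]:
    """Shuffle positives into ``n_folds`` near-equal parts and sample negatives.

    Deterministic given ``seed``.  Per fold the training negatives match
    the training positives in count; every other unobserved pair is a test
    negative.
    """
    positives = b.positive_pairs()
    if positives.shape[0] < n_folds:
        raise ValueError(f"need at least {n_folds} positive pairs")
    unobserved = np.argwhere(b.values == 0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(positives.shape[0])
    parts = np.array_split(order, n_folds)
    folds = []
    for fold_id, part in enumerate(parts, start=1):
        test_pos = positives[part]
        train_mask = np.ones(positives.shape[0], dtype=bool)
        train_mask[part] = False
        train_pos = positives[train_mask]
        n_train_neg = train_pos.shape[0]
        if unobserved.shape[0] < n_train_neg + 1:
            raise ValueError("not enough unobserved pairs to sample negatives")
        chosen = rng.choice(unobserved.shape[0], size=n_train_neg, replace=False)
        neg_mask = np.zeros(unobserved.shape[0], dtype=bool)
        neg_mask[chosen] = True
        folds.append(FoldSplit(
            fold_id=fold_id, seed=seed,
            train_pos=train_pos, train_neg=unobserved[neg_mask],
            test_pos=test_pos, test_neg=unobserved[~neg_mask],
        ))
    return folds


def mask_training_graph(b: AssociationMatrix, fold: FoldSplit) -> AssociationMatrix:
    """Copy of the association matrix with the fold's test positives zeroed."""
    values = b.values.copy()
    values[fold.test_pos[:, 0], fold.test_pos[:, 1]] = 0
    return AssociationMatrix(values, b.drug_ids, b.microbe_ids)


def per_drug_auc_aupr(scores: np.ndarray, fold: FoldSplit,
                      drug: int) -> tuple[float, float] | None:
    """(AUC, AUPR) over one drug's held-out candidates; None if not evaluable.

    ``scores`` is the full (n_drugs, n_microbes) association-score matrix.
    AUC uses mean ranks for ties; AUPR is step-wise average precision.
    """
    pos, neg = fold.test_pairs_of_drug(drug)
    if pos.size == 0 or neg.size == 0:
        return None
    y_true = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    y_score = np.concatenate([scores[drug, pos], scores[drug, neg]])
    return (float(roc_auc_score(y_true, y_score)),
            float(average_precision_score(y_true, y_score)))


def topk_recall(scores: np.ndarray, fold: FoldSplit, k: int) -> float:
    """Mean over evaluable drugs of the fraction of test positives in the top k.

    Candidates are the drug's test pairs; ties are broken deterministically
    by (-score, microbe index) stable sort.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    recalls = []
    for drug in range(scores.shape[0]):
        pos, neg = fold.test_pairs_of_drug(drug)
        if pos.size == 0:
            continue
        candidates = np.concatenate([pos, neg])
        cand_scores = scores[drug, candidates]
        order = np.lexsort((candidates, -cand_scores))
        top = set(candidates[order[:k]].tolist())
        recalls.append(sum(1 for m in pos if m in top) / pos.size)
    if not recalls:
        raise ValueError("no evaluable drugs in this fold")
    return float(np.mean(recalls))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p via DP over the signed-rank null distribution.

    Mean ranks may be half-integers, so the DP runs over doubled ranks.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_low = counts[:w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def paired_wilcoxon(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; all-zero differences give the degenerate
    p = 1.  Exact enumeration for n <= 25, normal approximation with
    continuity correction beyond.
    """
    a = np.asarray(metric_a, dtype=float)
    bvec = np.asarray(metric_b, dtype=float)
    if a.shape != bvec.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - bvec
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(ranks, w_plus)
    res = stats.wilcoxon(a, bvec, zero_method="wilcox", correction=True,
                         alternative="two-sided", method="approx")
    return float(res.pvalue)


def evaluate_fold(scores: np.ndarray, fold: FoldSplit,
                  topk: tuple[int, ...] = (3, 6, 9, 12),
                  config: dict | None = None) -> MetricReport:
    """Per-drug metrics and top-k recall curve for one fold's score matrix."""
    drugs, aucs, auprs = [], [], []
    skipped = 0
    for drug in range(scores.shape[0]):
        result = per_drug_auc_aupr(scores, fold, drug)
        if result is None:  # no test positive (or no negative) for this drug
            skipped += 1
            continue
        drugs.append(drug)
        aucs.append(result[0])
        auprs.append(result[1])
    if not drugs:
        raise ValueError("no evaluable drugs in this fold")
    aucs_arr = np.asarray(aucs)
    auprs_arr = np.asarray(auprs)
    return MetricReport(
        fold_id=fold.fold_id,
        drug_indices=np.asarray(drugs),
        per_drug_auc=aucs_arr,
        per_drug_aupr=auprs_arr,
        mean_auc=float(aucs_arr.mean()),
        mean_aupr=float(auprs_arr.mean()),
        topk_recall={k: topk_recall(scores, fold, k) for k in topk},
        n_drugs_evaluated=len(drugs),
        n_drugs_skipped=skipped,
        config=config or {},
    )
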