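"""Cross-validation folds, per-drug ranking metrics, Wilcoxon test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ngmda import (AssociationMatrix, make_cv_folds, mask_training_graph,
                   paired_wilcoxon, per_drug_auc_aupr, topk_recall)
from ngmda.evaluation import FoldSplit, evaluate_fold


def rank_auc(pos_scores, neg_scores):
    """Mann-Whitney AUC with mean ranks for ties (independent oracle)."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(scores)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def step_aupr(pos_scores, neg_scores):
    """Average precision by direct enumeration (no score ties assumed)."""
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    order = np.argsort(-scores)
    labels = labels[order]
    tp = np.cumsum(labels)
    precision = tp / np.arange(1, len(labels) + 1)
    return float((precision * labels).sum() / labels.sum())


def make_fold(pos_scores, neg_scores):
    """Single-drug fold whose test pairs carry the given score layout."""
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    test_pos = np.array([[0, j] for j in range(n_pos)])
    test_neg = np.array([[0, n_pos + j] for j in range(n_neg)])
    scores = np.concatenate([pos_scores, neg_scores])[None, :]
    fold = FoldSplit(fold_id=1, seed=0, train_pos=np.empty((0, 2), int),
                     train_neg=np.empty((0, 2), int), test_pos=test_pos,
                     test_neg=test_neg)
    return scores, fold


class TestFolds:
    @pytest.fixture
    def assoc(self):
        rng = np.random.default_rng(0)
        values = (rng.random((12, 10)) < 0.15).astype(int)
        values[values.sum(axis=1) == 0, 0] = 1
        return AssociationMatrix(values, [f"d{i}" for i in range(12)],
                                 [f"m{j}" for j in range(10)])

    def test_even_split_of_ten_positives(self):
        values = np.zeros((5, 4), dtype=int)
        values[:, 0] = 1
        values[:, 1] = 1
        assoc = AssociationMatrix(values, list("abcde"), list("wxyz"))
        folds = make_cv_folds(assoc, seed=0)
        assert [len(f.test_pos) for f in folds] == [2, 2, 2, 2, 2]

    def test_partition_and_disjointness(self, assoc):
        folds = make_cv_folds(assoc, seed=1)
        all_pos = {tuple(p) for p in assoc.positive_pairs()}
        tested = [tuple(p) for f in folds for p in f.test_pos]
        assert set(tested) == all_pos and len(tested) == len(all_pos)
        for f in folds:
            train_pos = {tuple(p) for p in f.train_pos}
            test_pos = {tuple(p) for p in f.test_pos}
            train_neg = {tuple(p) for p in f.train_neg}
            test_neg = {tuple(p) for p in f.test_neg}
            assert train_pos | test_pos == all_pos and not train_pos & test_pos
            assert not train_neg & test_neg
            assert len(f.train_neg) == len(f.train_pos)
            unobserved = {tuple(p) for p in np.argwhere(assoc.values == 0)}
            assert train_neg | test_neg == unobserved

    def test_determinism_and_seed_sensitivity(self, assoc):
        a = make_cv_folds(assoc, seed=5)
        b = make_cv_folds(assoc, seed=5)
        c = make_cv_folds(assoc, seed=6)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test_pos, fb.test_pos)
            np.testing.assert_array_equal(fa.train_neg, fb.train_neg)
        assert any(not np.array_equal(fa.train_neg, fc.train_neg)
                   for fa, fc in zip(a, c))

    def test_too_few_positives_rejected(self):
        assoc = AssociationMatrix(np.eye(2, dtype=int), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            make_cv_folds(assoc, seed=0)

    def test_masking(self, assoc):
        fold = make_cv_folds(assoc, seed=2)[0]
        masked = mask_training_graph(assoc, fold)
        assert masked.values[fold.test_pos[:, 0], fold.test_pos[:, 1]].sum() == 0
        assert masked.values[fold.train_pos[:, 0], fold.train_pos[:, 1]].min() == 1
        again = mask_training_graph(masked, fold)
        np.testing.assert_array_equal(again.values, masked.values)


class TestPerDrugMetrics:
    def test_perfect_and_mid_ranking(self):
        scores, fold = make_fold(np.array([0.9]), np.array([0.1, 0.2]))
        auc, aupr = per_drug_auc_aupr(scores, fold, 0)
        assert auc == 1.0 and aupr == 1.0
        scores, fold = make_fold(np.array([0.5]), np.array([0.6, 0.4]))
        auc, _ = per_drug_auc_aupr(scores, fold, 0)
        assert auc == pytest.approx(0.5)

    def test_all_tied_gives_half(self):
        scores, fold = make_fold(np.array([0.3, 0.3]), np.array([0.3, 0.3]))
        auc, _ = per_drug_auc_aupr(scores, fold, 0)
        assert auc == pytest.approx(0.5)

    def test_drug_without_positives_returns_none(self):
        scores, fold = make_fold(np.array([0.9]), np.array([0.1]))
        fold.test_pos = np.empty((0, 2), dtype=int)
        assert per_drug_auc_aupr(scores, fold, 0) is None

    def test_matches_rank_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_pos = int(rng.integers(1, 6))
            n_neg = int(rng.integers(1, 30))
            pos = rng.random(n_pos)
            neg = rng.random(n_neg)
            scores, fold = make_fold(pos, neg)
            auc, aupr = per_drug_auc_aupr(scores, fold, 0)
            assert abs(auc - rank_auc(pos, neg)) < 1e-10
            assert abs(aupr - step_aupr(pos, neg)) < 1e-10

    def test_random_scores_concentrate_at_half(self):
        """Mean per-drug AUC of a random scorer is ~0.5; AUPR ~ prevalence."""
        rng = np.random.default_rng(4)
        aucs, auprs = [], []
        for _ in range(200):
            pos = rng.random(10)   # enough positives that AP ~ prevalence
            neg = rng.random(90)
            scores, fold = make_fold(pos, neg)
            auc, aupr = per_drug_auc_aupr(scores, fold, 0)
            aucs.append(auc)
            auprs.append(aupr)
        assert abs(np.mean(aucs) - 0.5) < 0.05
        assert abs(np.mean(auprs) - 0.1) < 0.05


class TestTopKRecall:
    def test_hand_enumerated_example(self):
        # two positives ranked 1st and 5th among 6 candidates, k=3 -> 0.5
        pos = np.array([0.95, 0.30])
        neg = np.array([0.8, 0.7, 0.6, 0.1])
        scores, fold = make_fold(pos, neg)
        assert topk_recall(scores, fold, 3) == pytest.approx(0.5)

    def test_k_covers_all_candidates(self):
        scores, fold = make_fold(np.array([0.5, 0.1]), np.array([0.9, 0.7]))
        assert topk_recall(scores, fold, 4) == 1.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(5)
        scores, fold = make_fold(rng.random(4), rng.random(20))
        values = [topk_recall(scores, fold, k) for k in range(1, 25)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_invalid_k(self):
        scores, fold = make_fold(np.array([0.5]), np.array([0.1]))
        with pytest.raises(ValueError):
            topk_recall(scores, fold, 0)


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        v = np.array([0.1, 0.5, 0.9])
        assert paired_wilcoxon(v, v) == 1.0

    def test_three_positive_differences(self):
        a = np.array([0.5, 0.6, 0.7])
        b = a - np.array([0.1, 0.2, 0.3])
        assert paired_wilcoxon(a, b) == pytest.approx(0.25)

    def test_matches_sign_pattern_enumeration(self):
        """Exact branch equals direct enumeration over all sign patterns."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            diff = rng.standard_normal(n)
            diff[diff == 0] = 0.5
            p_impl = paired_wilcoxon(diff, np.zeros(n))
            ranks = stats.rankdata(np.abs(diff))
            w_obs = ranks[diff > 0].sum()
            stats_all = [ranks[list(signs)].sum() if signs else 0.0
                         for r in range(n + 1)
                         for signs in itertools.combinations(range(n), r)]
            stats_all = np.array(stats_all)
            p_lo = (stats_all <= w_obs + 1e-12).mean()
            p_hi = (stats_all >= w_obs - 1e-12).mean()
            expected = min(1.0, 2 * min(p_lo, p_hi))
            assert p_impl == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.random(12)
            b = rng.random(12)
            expected = stats.wilcoxon(a, b, method="exact").pvalue
            assert paired_wilcoxon(a, b) == pytest.approx(expected, rel=1e-9)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.random(60)
        b = a + rng.normal(0.05, 0.1, 60)
        expected = stats.wilcoxon(a, b, correction=True, method="approx").pvalue
        assert paired_wilcoxon(a, b) == pytest.approx(expected, rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.ones(3), np.ones(4))


def test_evaluate_fold_reports_counts():
    rng = np.random.default_rng(9)
    n_d, n_m = 8, 10
    values = (rng.random((n_d, n_m)) < 0.2).astype(int)
    values[0] = 0  # drug 0 has no positives at all
    values[1, 0] = 1
    assoc = AssociationMatrix(values, [f"d{i}" for i in range(n_d)],
                              [f"m{j}" for j in range(n_m)])
    fold = make_cv_folds(assoc, seed=1)[0]
    report = evaluate_fold(rng.random((n_d, n_m)), fold, topk=(3,))
    assert report.n_drugs_evaluated + report.n_drugs_skipped == n_d
    assert 0.0 <= report.mean_auc <= 1.0
    assert set(report.topk_recall) == {3}
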