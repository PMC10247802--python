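import numpy as np
import pytest

from dti.errors import (
    DimensionError,
    MetricError,
    SamplingError,
    ValidationError,
)
from dti.evaluation import (
    SamplingSpec,
    compute_metrics,
    make_cv_folds,
    paired_t_test,
    rank_novel_interactions,
    run_cross_validation,
    sample_negative_pairs,
)

from conftest import light_predictor_config


def auc_by_pair_counting(labels, scores):
    """O(P*N) Mann-Whitney AUC with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_by_step_integration(labels, scores):
    """Area under the precision-recall step curve: sum dR * P at each step."""
    order = np.argsort(-scores, kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    P = labels.sum()
    tp = fp = 0
    area, prev_recall = 0.0, 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / P
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestSampleNegativePairs:
    def test_sample_avoids_positives_and_matches_ratio(self):
        X = np.zeros((3, 3))
        X[0, 0] = X[1, 2] = 1
        neg = sample_negative_pairs(X, SamplingSpec(ratio=1, seed=0))
        assert neg.shape == (2, 2)
        assert all(X[i, j] == 0 for i, j in neg)

    def test_ratio_too_large_rejected(self):
        X = np.ones((3, 3))
        X[0, 0] = 0
        X[1, 1] = 0  # 7 positives, 2 zeros
        with pytest.raises(SamplingError):
            sample_negative_pairs(X, SamplingSpec(ratio=1, seed=0))

    def test_fixed_seed_reproduces_sample(self, tiny_bundle):
        bundle, _ = tiny_bundle
        a = sample_negative_pairs(bundle.X, SamplingSpec(ratio=3, seed=5))
        b = sample_negative_pairs(bundle.X, SamplingSpec(ratio=3, seed=5))
        np.testing.assert_array_equal(a, b)
        c = sample_negative_pairs(bundle.X, SamplingSpec(ratio=3, seed=6))
        assert not np.array_equal(a, c)


class TestMakeCvFolds:
    def test_100_pairs_give_ten_folds_of_ten(self):
        split = make_cv_folds(np.r_[np.ones(40), np.zeros(60)], seed=0)
        sizes = np.bincount(split.fold_ids, minlength=10)
        assert list(sizes) == [10] * 10

    def test_103_pairs_give_sizes_ten_or_eleven(self):
        split = make_cv_folds(np.r_[np.ones(43), np.zeros(60)], seed=0)
        sizes = np.bincount(split.fold_ids, minlength=10)
        assert set(sizes) <= {10, 11}
        assert sizes.sum() == 103

    def test_stratification_puts_four_positives_in_every_fold(self):
        labels = np.r_[np.ones(40), np.zeros(60)]
        split = make_cv_folds(labels, seed=3)
        for fold in range(10):
            assert labels[split.fold_indices(fold)].sum() == 4

    def test_folds_partition_all_pairs(self):
        labels = np.r_[np.ones(37), np.zeros(100)]
        split = make_cv_folds(labels, seed=1)
        seen = np.concatenate([split.fold_indices(f) for f in range(10)])
        assert sorted(seen) == list(range(137))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            make_cv_folds(np.ones(5), seed=0)


class TestComputeMetrics:
    def test_perfect_separation_scores_one_everywhere(self):
        labels = np.r_[np.ones(5), np.zeros(5)]
        scores = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        row = compute_metrics(labels, scores)
        for name in ("sensitivity", "specificity", "precision", "f1", "mcc",
                     "auc_roc", "aupr"):
            assert getattr(row, name) == 1.0

    def test_all_predicted_positive(self):
        labels = np.r_[np.ones(3), np.zeros(7)]
        row = compute_metrics(labels, np.full(10, 0.9))
        assert row.sensitivity == 1.0
        assert row.specificity == 0.0
        assert row.precision == pytest.approx(0.3)

    def test_hand_confusion_case(self):
        """TP=2 FP=1 TN=3 FN=1: precision=recall=F1=2/3, MCC=5/12."""
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.1, 0.7, 0.2, 0.2, 0.1])
        row = compute_metrics(labels, scores, threshold=0.5)
        assert (row.tp, row.fp, row.tn, row.fn) == (2, 1, 3, 1)
        assert row.precision == pytest.approx(2 / 3)
        assert row.sensitivity == pytest.approx(2 / 3)
        assert row.f1 == pytest.approx(2 / 3)
        assert row.mcc == pytest.approx(5 / 12)

    def test_undefined_precision_reported_as_zero_with_flag(self):
        labels = np.array([1, 0, 0])
        row = compute_metrics(labels, np.array([0.1, 0.2, 0.3]), threshold=0.5)
        assert row.precision == 0.0
        assert "precision_undefined" in row.flags

    def test_one_class_input_rejected(self):
        with pytest.raises(MetricError):
            compute_metrics(np.ones(4), np.random.rand(4))

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_and_aupr_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        labels = (rng.random(n) < 0.3).astype(int)
        if labels.sum() in (0, n):
            labels[:2] = [0, 1]
        # quantized scores force ties
        scores = np.round(rng.random(n), 2)
        row = compute_metrics(labels, scores)
        assert row.auc_roc == pytest.approx(
            auc_by_pair_counting(labels, scores), abs=1e-10)
        assert row.aupr == pytest.approx(
            aupr_by_step_integration(labels, scores), abs=1e-10)

    def test_aupr_at_least_prevalence_under_signal(self, rng):
        labels = (rng.random(300) < 0.2).astype(int)
        scores = labels * 0.5 + rng.random(300) * 0.5
        row = compute_metrics(labels, scores)
        assert row.aupr >= labels.mean()


class TestPairedTTest:
    def test_identical_vectors_flagged_p_one(self):
        r = paired_t_test([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert r.degenerate and r.p_value == 1.0

    def test_constant_nonzero_difference_flagged_p_zero(self):
        r = paired_t_test([1, 2, 3, 4], [0, 1, 2, 3])
        assert r.degenerate and r.p_value == 0.0 and r.t == np.inf

    def test_matches_closed_form(self):
        a = np.array([0.9, 0.8, 0.85, 0.95])
        b = np.array([0.7, 0.65, 0.6, 0.8])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist
        p_expected = 2 * tdist.sf(abs(t_expected), len(d) - 1)
        r = paired_t_test(a, b)
        assert not r.degenerate
        assert r.t == pytest.approx(t_expected, abs=1e-12)
        assert r.p_value == pytest.approx(p_expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t_test([1, 2], [1, 2, 3])


class TestRankNovelInteractions:
    def test_all_below_threshold_gives_empty_list(self):
        assert rank_novel_interactions(np.full((2, 2), 0.5), np.zeros((2, 2))) == []

    def test_known_positives_masked_even_at_score_one(self):
        S = np.array([[1.0, 0.95], [0.2, 0.99]])
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        ranked = rank_novel_interactions(S, X, threshold=0.9)
        assert ranked == [(1, 1, 0.99), (0, 1, 0.95)]

    def test_constructed_seven_novel_entries_in_score_order(self, rng):
        S = rng.random((6, 8)) * 0.5
        X = np.zeros((6, 8))
        cells = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (0, 7)]
        for v, (i, j) in enumerate(cells):
            S[i, j] = 0.90 + 0.01 * v
        ranked = rank_novel_interactions(S, X, threshold=0.9)
        assert len(ranked) == 7
        assert [r[2] for r in ranked] == sorted((r[2] for r in ranked),
                                                reverse=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            rank_novel_interactions(np.zeros((2, 3)), np.zeros((3, 2)))


@pytest.fixture(scope="module")
def tiny_cv_report(tiny_bundle):
    bundle, _ = tiny_bundle
    cfg = light_predictor_config(bundle.m + bundle.n, epochs=2,
                                 batch_size=128)
    return run_cross_validation(bundle, "dedti",
                                SamplingSpec(ratio=3, seed=11),
                                predictor_config=cfg)


class TestRunCrossValidation:
    def test_report_structure(self, tiny_cv_report):
        rep = tiny_cv_report
        assert len(rep.folds) == 10
        d = rep.to_dict()
        assert set(d["mean"]) == {"sensitivity", "specificity", "precision",
                                  "f1", "mcc", "auc_roc", "aupr"}
        for row in rep.folds:
            assert 0.0 <= row.auc_roc <= 1.0
            assert -1.0 <= row.mcc <= 1.0

    def test_aggregates_consistent_with_folds(self, tiny_cv_report):
        rep = tiny_cv_report
        per_fold = [r.auc_roc for r in rep.folds]
        assert rep.mean["auc_roc"] == pytest.approx(np.mean(per_fold), abs=1e-12)
        assert rep.std["auc_roc"] == pytest.approx(np.std(per_fold, ddof=1),
                                                   abs=1e-12)

    def test_deterministic_repeat(self, tiny_bundle, tiny_cv_report):
        bundle, _ = tiny_bundle
        cfg = light_predictor_config(bundle.m + bundle.n, epochs=2,
                                     batch_size=128)
        again = run_cross_validation(bundle, "dedti",
                                     SamplingSpec(ratio=3, seed=11),
                                     predictor_config=cfg)
        for r1, r2 in zip(tiny_cv_report.folds, again.folds):
            assert r1 == r2

    def test_unknown_mode_rejected(self, tiny_bundle):
        bundle, _ = tiny_bundle
        with pytest.raises(ValidationError):
            run_cross_validation(bundle, "other", SamplingSpec())
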