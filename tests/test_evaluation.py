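"""Confusion metrics, ROC/AUC, and the nested CV harness."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tlecortex as tc
from tlecortex.evaluation import evaluate_outer_fold, pooled_counts


class TestMetrics:
    def test_reconstructed_confusion_row(self):
        """TP=36 FN=5 TN=58 FP=0 (n=41 patients, 58 controls)."""
        m = tc.compute_metrics(tc.ConfusionCounts(TP=36, FN=5, TN=58, FP=0))
        pct = m.as_percent()
        assert pct["accuracy"] == pytest.approx(94.95, abs=5e-3)
        assert pct["sensitivity"] == pytest.approx(87.80, abs=5e-3)
        assert pct["specificity"] == pytest.approx(100.0)

    def test_perfect_two_subject_case(self):
        m = tc.compute_metrics(tc.ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    @given(
        tp=st.integers(0, 200), tn=st.integers(0, 200),
        fp=st.integers(0, 200), fn=st.integers(0, 200),
    )
    @settings(max_examples=100, derandomize=True)
    def test_accuracy_is_prevalence_weighted_mean(self, tp, tn, fp, fn):
        """accuracy = (sens*(TP+FN) + spec*(TN+FP)) / total, exactly."""
        if tp + tn + fp + fn == 0:
            return
        c = tc.ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
        m = tc.compute_metrics(c)
        sens = m.sensitivity if m.sensitivity is not None else 0.0
        spec = m.specificity if m.specificity is not None else 0.0
        expect = (sens * (tp + fn) + spec * (tn + fp)) / c.total
        assert m.accuracy == pytest.approx(expect, abs=1e-12)

    def test_undefined_ratios_are_flagged_not_nan(self):
        m = tc.compute_metrics(tc.ConfusionCounts(TP=0, FN=0, TN=3, FP=1))
        assert m.sensitivity is None
        assert m.specificity == 0.75

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tc.ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


class TestROC:
    def test_perfectly_ordered_scores_auc_1(self):
        roc, auc = tc.compute_roc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_four_point_worked_example(self):
        """3 of 4 positive/negative pairs concordant -> AUC 0.75."""
        _, auc = tc.compute_roc(np.array([0.9, 0.8, 0.4, 0.1]), np.array([1, 0, 1, 0]))
        assert auc == pytest.approx(0.75, abs=1e-12)

    def test_trapezoid_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_pos = int(rng.integers(2, 20))
            n_neg = int(rng.integers(2, 20))
            scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # ties likely
            labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
            _, auc = tc.compute_roc(scores, labels)
            u = stats.mannwhitneyu(scores[:n_pos], scores[n_pos:]).statistic
            assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(100):
            scores = rng.normal(size=40)
            labels = np.r_[np.ones(20, int), np.zeros(20, int)]
            aucs.append(tc.compute_roc(scores, labels)[1])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tc.compute_roc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_roc_monotone(self):
        rng = np.random.default_rng(3)
        roc, _ = tc.compute_roc(rng.normal(size=30), rng.integers(0, 2, 30))
        xs, ys = zip(*roc)
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert all(b >= a for a, b in zip(ys, ys[1:]))


def _toy_separable_table():
    labels = [tc.parse_label("lh_entorhinal_CSA"), tc.parse_label("rh_cuneus_CTh")]
    subjects = [
        tc.SubjectRecord("p1", "LTLE", 25, "M", "1.5T"),
        tc.SubjectRecord("p2", "LTLE", 26, "F", "1.5T"),
        tc.SubjectRecord("c1", "NC", 24, "M", "3.0T"),
        tc.SubjectRecord("c2", "NC", 27, "F", "3.0T"),
    ]
    values = np.array([[10.0, 0.1], [11.0, -0.2], [-10.0, 0.15], [-11.0, -0.1]])
    return tc.CorticalFeatureTable(subjects=subjects, labels=labels, values=values)


class TestNestedCV:
    def test_separable_toy_perfect_at_k1(self):
        cfg = tc.reduced_cv_config(max_k=2, lambda_grid=(0.1,), seed=0)
        ev = tc.nested_cv_evaluate(_toy_separable_table(), tc.LTLE_NC, "ttest", cfg)
        assert ev.optimal_k == 1
        assert ev.optimal_metrics.accuracy == 1.0
        assert ev.auc == 1.0

    def test_determinism(self, default_cohort):
        sub = tc.subset(default_cohort, tc.LTLE_RTLE, {"MCu"})
        cfg = tc.reduced_cv_config(max_k=5, seed=4)
        a = tc.nested_cv_evaluate(sub, tc.LTLE_RTLE, "ttest", cfg)
        b = tc.nested_cv_evaluate(sub, tc.LTLE_RTLE, "ttest", cfg)
        assert a.to_dict() == b.to_dict()

    def test_held_out_subject_cannot_influence_fold_fit(self, default_cohort):
        """Perturbing the held-out features changes predictions only through
        the frozen fold model, never the ranking or the model itself."""
        sub = tc.subset(default_cohort, tc.LTLE_NC, {"CSA"})
        X, y = sub.values, (sub.groups == "LTLE").astype(int)
        cfg = tc.reduced_cv_config(max_k=3, seed=1)
        X_train, y_train = X[1:], y[1:]
        test_a = X[0]
        test_b = X[0] + 1e3  # wildly perturbed held-out subject
        probe = X[0] * 0.5
        pa, sa, rank_a = evaluate_outer_fold(
            X_train, y_train, np.vstack([test_a, probe]), "ttest", cfg,
            k_values=[1, 2, 3], labels=sub.labels, fold_index=0,
        )
        pb, sb, rank_b = evaluate_outer_fold(
            X_train, y_train, np.vstack([test_b, probe]), "ttest", cfg,
            k_values=[1, 2, 3], labels=sub.labels, fold_index=0,
        )
        np.testing.assert_array_equal(rank_a.order, rank_b.order)
        # the shared probe row gets identical predictions and scores
        np.testing.assert_array_equal(pa[1], pb[1])
        np.testing.assert_allclose(sa[1], sb[1], rtol=1e-12)

    def test_noise_features_beyond_optimum_never_beat_separable_max(self):
        rng = np.random.default_rng(6)
        table = _toy_separable_table()
        # add 6 pure-noise features
        noise_labels = [l for l in tc.canonical_labels(["GMV"])[:6]]
        values = np.hstack([table.values, rng.normal(size=(4, 6))])
        table = tc.CorticalFeatureTable(
            subjects=table.subjects, labels=table.labels + noise_labels, values=values
        )
        cfg = tc.reduced_cv_config(max_k=8, lambda_grid=(0.1,), seed=2)
        ev = tc.nested_cv_evaluate(table, tc.LTLE_NC, "ttest", cfg)
        assert max(m.accuracy for m in ev.curve) <= ev.curve[ev.optimal_k - 1].accuracy

    def test_unknown_method_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="unknown selection method"):
            tc.nested_cv_evaluate(default_cohort, tc.LTLE_NC, "lasso")

    def test_paper_compat_mode_warns_and_runs(self):
        cfg = tc.reduced_cv_config(max_k=2, leakage_mode="paper_compat", seed=0)
        with pytest.warns(UserWarning, match="optimistic"):
            ev = tc.nested_cv_evaluate(_toy_separable_table(), tc.LTLE_NC, "ttest", cfg)
        assert ev.leakage_mode == "paper_compat"

    def test_pooled_counts_partition_subjects(self, default_cohort):
        sub = tc.subset(default_cohort, tc.RTLE_NC, {"CTh"})
        cfg = tc.reduced_cv_config(max_k=3, seed=3)
        ev = tc.nested_cv_evaluate(sub, tc.RTLE_NC, "scdrm", cfg)
        for c in ev.counts:
            assert c.total == 34 + 58

    def test_permuted_labels_fall_to_majority_rate(self, null_cohort):
        """Label permutation destroys the signal: accuracy sits at chance."""
        sub = tc.subset(null_cohort, tc.LTLE_NC, {"CSA"})
        cfg = tc.reduced_cv_config(max_k=5, seed=5)
        rng = np.random.default_rng(12)
        accs = []
        for _ in range(5):
            groups = np.array([s.group for s in sub.subjects])
            rng.shuffle(groups)
            recs = [
                replace(s, group=g, subject_id=f"S{i}")
                for i, (s, g) in enumerate(zip(sub.subjects, groups))
            ]
            ptab = tc.CorticalFeatureTable(subjects=recs, labels=sub.labels, values=sub.values)
            ev = tc.nested_cv_evaluate(ptab, tc.LTLE_NC, "ttest", cfg)
            accs.append(ev.optimal_metrics.accuracy)
        majority = 58 / 99
        assert abs(np.mean(accs) - majority) < 0.12  # loose unit check; the
        # tight 20-permutation band is asserted in the acceptance suite


def test_pooled_counts_against_manual_confusion():
    y = np.array([1, 1, 0, 0, 1])
    p = np.array([1, 0, 0, 1, 1])
    c = pooled_counts(y, p)
    assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 1, 1)
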