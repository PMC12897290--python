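"""Fold planning, metrics, bootstrap CIs and nested CV behavior."""

import numpy as np
import pytest

from bdtaskfmri.classify import (
    CLASSIFIER_FAMILIES,
    ClassifierSpec,
    bootstrap_ci,
    compute_metrics,
    make_fold_plan,
    run_nested_cv,
)


class TestFoldPlan:
    def _labels(self, n_pos=10, n_neg=10):
        labels = {f"p{i:02d}": 1 for i in range(n_pos)}
        labels.update({f"c{i:02d}": 0 for i in range(n_neg)})
        return labels

    def test_test_sets_partition_cohort(self):
        labels = self._labels()
        plan = make_fold_plan(labels, seed=3)
        seen = [s for _, test in plan.outer for s in test]
        assert sorted(seen) == sorted(labels)
        assert len(seen) == len(set(seen))

    def test_train_test_disjoint_and_complete(self):
        labels = self._labels()
        plan = make_fold_plan(labels, seed=3)
        for train, test in plan.outer:
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(labels)

    def test_stratification_within_one_subject(self):
        labels = self._labels(n_pos=13, n_neg=9)
        plan = make_fold_plan(labels, seed=1)
        ratios = []
        for _, test in plan.outer:
            pos = sum(labels[s] for s in test)
            ratios.append(pos)
        assert max(ratios) - min(ratios) <= 1

    def test_deterministic_and_seed_sensitive(self):
        labels = self._labels()
        a = make_fold_plan(labels, seed=42)
        b = make_fold_plan(labels, seed=42)
        c = make_fold_plan(labels, seed=43)
        assert a.outer == b.outer
        assert a.outer != c.outer

    def test_small_class_rejected(self):
        labels = self._labels(n_pos=4, n_neg=10)
        with pytest.raises(ValueError, match="fewer than 5"):
            make_fold_plan(labels, seed=0, n_outer=5)


class TestComputeMetrics:
    def test_hand_worked_oracle(self):
        # tp=3, tn=2, fp=1, fn=2
        y_true = [1, 1, 1, 1, 1, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.6, 0.2, 0.1]
        m = compute_metrics(y_true, y_pred, scores)
        assert m["accuracy"] == pytest.approx(100 * 5 / 8)
        assert m["sensitivity"] == pytest.approx(100 * 3 / 5)
        assert m["specificity"] == pytest.approx(100 * 2 / 3)
        assert m["ppv"] == pytest.approx(100 * 3 / 4)
        assert m["npv"] == pytest.approx(100 * 2 / 4)
        assert m["fdr"] == pytest.approx(100 * 1 / 4)
        assert m["f1"] == pytest.approx(2 * 75 * 60 / (75 + 60))
        # rank AUC by hand: pairs (pos, neg) with score_pos > score_neg
        # positives .9 .8 .7 .4 .3 vs negatives .6 .2 .1: 13/15 concordant
        assert m["auc"] == pytest.approx(100 * 13 / 15)
        assert m["confusion"] == {"tp": 3, "tn": 2, "fp": 1, "fn": 2}

    def test_perfect_and_inverted_auc(self):
        y = [0, 0, 1, 1]
        m = compute_metrics(y, y, [0.1, 0.2, 0.8, 0.9])
        assert m["auc"] == 100.0 and m["accuracy"] == 100.0 and m["fdr"] == 0.0
        m2 = compute_metrics(y, y, [0.9, 0.8, 0.2, 0.1])
        assert m2["auc"] == 0.0

    def test_identities_hold_under_fuzz(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            scores = rng.random(n)
            m = compute_metrics(y_true, y_pred, scores)
            c = m["confusion"]
            assert c["tp"] + c["tn"] + c["fp"] + c["fn"] == n
            if np.isfinite(m["ppv"]):
                assert m["fdr"] == pytest.approx(100.0 - m["ppv"])
            if np.isfinite(m["accuracy"]):
                assert m["accuracy"] == pytest.approx(
                    100.0 * (c["tp"] + c["tn"]) / n
                )

    def test_undefined_ratios_are_nan(self):
        m = compute_metrics([0, 0, 0], [0, 0, 0], [0.1, 0.2, 0.3])
        assert np.isnan(m["sensitivity"]) and np.isnan(m["ppv"])
        assert np.isnan(m["auc"])  # one-class pool
        assert m["specificity"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no pooled"):
            compute_metrics([], [], [])


class TestBootstrapCI:
    def test_deterministic(self):
        y = np.array([0, 1] * 10)
        pred = np.array([0, 1] * 9 + [1, 0])
        s = np.linspace(0, 1, 20)
        a = bootstrap_ci(y, pred, s, n_boot=500, seed=9)
        b = bootstrap_ci(y, pred, s, n_boot=500, seed=9)
        assert a == b

    def test_degenerate_predictions_give_tight_ci(self):
        y = np.array([0, 1] * 15)
        out = bootstrap_ci(y, y, np.where(y == 1, 0.9, 0.1), n_boot=300, seed=0)
        assert out["accuracy_ci"] == (1.0, 1.0)
        assert out["auc_ci"] == (1.0, 1.0)

    def test_one_class_resamples_counted_and_excluded(self):
        # tiny n makes one-class resamples likely
        y = np.array([0, 1, 1])
        out = bootstrap_ci(y, y, np.array([0.1, 0.8, 0.9]), n_boot=2000, seed=1)
        assert out["excluded_one_class"] > 0
        # P(all-1) + P(all-0) = (2/3)^3 + (1/3)^3 = 1/3
        assert out["excluded_one_class"] == pytest.approx(2000 / 3, rel=0.2)
        lo, hi = out["auc_ci"]
        assert 0.0 <= lo <= hi <= 1.0

    def test_ci_brackets_point_estimate(self, rng):
        y = rng.integers(0, 2, 40)
        scores = np.clip(y + rng.normal(0, 0.8, 40), 0, 1)
        pred = (scores > 0.5).astype(int)
        out = bootstrap_ci(y, pred, scores, n_boot=1000, seed=5)
        acc = (y == pred).mean()
        lo, hi = out["accuracy_ci"]
        assert lo <= acc <= hi


class TestClassifierSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("deep_net")

    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_estimators_fit_separable_data(self, family, rng):
        X = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(4, 1, (20, 4))])
        y = np.array([0] * 20 + [1] * 20)
        spec = ClassifierSpec(family)
        est = spec.make_estimator(seed=0)
        est.fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.95


class TestRunNestedCV:
    def test_strong_cohort_recovers_truth(self, prepared_strong, small_config):
        prepared, qc, config, truth = prepared_strong
        plan = make_fold_plan(prepared.labels, seed=config.seed, n_outer=4, n_inner=2)
        report = run_nested_cv(
            prepared,
            "Go-NoGo",
            ClassifierSpec("logistic_regression"),
            plan,
            rft_params=config.rft_params,
            n_boot=300,
        )
        assert report.skipped_folds == 0
        # every fold's abnormal ROI set equals the injected effect regions
        for fr in report.folds:
            assert set(fr.roi_names) == set(small_config.effect_rois)
        assert report.metrics["accuracy"] >= 90.0
        assert report.metrics["auc"] >= 90.0
        lo, hi = report.bootstrap["auc_ci"]
        assert lo <= report.metrics["auc"] / 100.0 <= hi
        assert report.importance is not None
        top = set(report.importance.top(3)["roi"])
        assert top == set(small_config.effect_rois)

    def test_pooled_predictions_cover_cohort_once(self, prepared_strong, small_config):
        prepared, qc, config, truth = prepared_strong
        plan = make_fold_plan(prepared.labels, seed=11, n_outer=4, n_inner=2)
        report = run_nested_cv(
            prepared,
            "Go-NoGo",
            ClassifierSpec("naive_bayes"),
            plan,
            rft_params=config.rft_params,
            compute_shap=False,
            n_boot=200,
        )
        n_pooled = sum(len(fr.test_ids) for fr in report.folds if not fr.skipped)
        assert n_pooled == len(prepared.ids)
        c = report.metrics["confusion"]
        assert c["tp"] + c["tn"] + c["fp"] + c["fn"] == n_pooled
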