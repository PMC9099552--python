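"""ROC/AUC, operating-point policies, leave-one-user-out, ablations."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from vbreath.evaluation import (
    AblationSpec,
    compute_auc,
    fpr_at_full_tpr,
    leave_one_user_out,
    run_ablation,
    tpr_at_zero_fpr,
)
from vbreath.pipeline import Label, build_dataset
from vbreath.signal_model import Device, Sensor


def lab(values, labels):
    """Zip scores with Label enums; labels given as 0/1."""
    return [
        (float(v), Label.INTOXICATED if y else Label.SOBER)
        for v, y in zip(values, labels)
    ]


def auc_pair_counting(scores_with_labels):
    """Brute-force oracle: enumerate all (intoxicated, sober) pairs."""
    pos = [s for s, l in scores_with_labels if l is Label.INTOXICATED]
    neg = [s for s, l in scores_with_labels if l is Label.SOBER]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def policy_sweep(scores_with_labels):
    """Exhaustive threshold sweep oracle for both operating-point policies.

    Candidate thresholds are every distinct score +/- a small epsilon;
    classification is score >= threshold.
    """
    scores = np.array([s for s, _ in scores_with_labels])
    y = np.array([l is Label.INTOXICATED for _, l in scores_with_labels])
    eps = 1e-9
    cands = np.unique(np.concatenate([scores - eps, scores, scores + eps]))
    best_fpr_at_tpr1, best_tpr_at_fpr0 = 1.0, 0.0
    for thr in cands:
        pred = scores >= thr
        tpr = np.mean(pred[y]) if y.any() else 0.0
        fpr = np.mean(pred[~y]) if (~y).any() else 0.0
        if y.any() and tpr == 1.0:
            best_fpr_at_tpr1 = min(best_fpr_at_tpr1, fpr)
        if (~y).any() and fpr == 0.0:
            best_tpr_at_fpr0 = max(best_tpr_at_fpr0, tpr)
    return best_fpr_at_tpr1, best_tpr_at_fpr0


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc(lab([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])) == 1.0
        assert compute_auc(lab([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0])) == 0.0

    def test_ties_count_half(self):
        assert compute_auc(lab([0.5, 0.5], [1, 0])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc(lab([0.5, 0.6], [1, 1]))

    def test_matches_pair_counting_oracle_and_sklearn(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid to force ties
            swl = lab(scores, y)
            got = compute_auc(swl)
            assert got == pytest.approx(auc_pair_counting(swl), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_negating_scores_complements_auc(self):
        rng = np.random.default_rng(3)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0])
        s = rng.random(len(y))
        assert compute_auc(lab(s, y)) + compute_auc(lab(-s, y)) == pytest.approx(1.0)


class TestPolicies:
    def test_fpr_at_full_tpr_example(self):
        swl = lab([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0])
        assert fpr_at_full_tpr(swl) == 0.5

    def test_separable_scores_give_extremes(self):
        swl = lab([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert fpr_at_full_tpr(swl) == 0.0
        assert tpr_at_zero_fpr(swl) == 1.0

    def test_all_equal_scores(self):
        swl = lab([0.5, 0.5, 0.5], [1, 0, 0])
        assert fpr_at_full_tpr(swl) == 1.0
        assert tpr_at_zero_fpr(swl) == 0.0

    def test_tpr_at_zero_fpr_example(self):
        swl = lab([0.9, 0.6, 0.7, 0.2], [1, 1, 0, 0])
        assert tpr_at_zero_fpr(swl) == 0.5

    def test_inverted_scores(self):
        swl = lab([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert tpr_at_zero_fpr(swl) == 0.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            fpr_at_full_tpr(lab([0.5], [0]))
        with pytest.raises(ValueError):
            tpr_at_zero_fpr(lab([0.5], [1]))

    def test_policies_match_exhaustive_sweep(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 1)
            swl = lab(scores, y)
            want_fpr, want_tpr = policy_sweep(swl)
            assert fpr_at_full_tpr(swl) == pytest.approx(want_fpr, abs=1e-12)
            assert tpr_at_zero_fpr(swl) == pytest.approx(want_tpr, abs=1e-12)


@pytest.fixture(scope="module")
def instances(strong_cohort):
    return build_dataset(strong_cohort, 240.0)


class TestLeaveOneUserOut:
    def test_each_subject_held_out_exactly_once(self, instances):
        result = leave_one_user_out(instances, "adaboost", seed=0)
        assert len(result.pooled_scores) == 30
        assert {s.subject_id for s in result.pooled_scores} == {
            i.subject_id for i in instances
        }
        assert result.confusion.sum() == 30

    def test_minimal_three_subject_case(self, instances):
        by_label = {Label.SOBER: [], Label.INTOXICATED: []}
        for inst in instances:
            by_label[inst.label].append(inst)
        tiny = by_label[Label.SOBER][:2] + by_label[Label.INTOXICATED][:1]
        result = leave_one_user_out(tiny, "naive_bayes", seed=0)
        assert len(result.pooled_scores) == 3

    def test_single_class_dataset_rejected(self, instances):
        sober_only = [i for i in instances if i.label is Label.SOBER]
        with pytest.raises(ValueError, match="single class"):
            leave_one_user_out(sober_only, "adaboost", seed=0)

    def test_too_few_instances_rejected(self, instances):
        with pytest.raises(ValueError, match="at least 3"):
            leave_one_user_out(instances[:2], "adaboost", seed=0)

    def test_held_out_subject_never_in_training_set(self, instances, monkeypatch):
        import vbreath.evaluation as ev

        captured = []
        orig_fit = ev.DetectionModel.fit

        def spy_fit(self, X, y):
            captured.append(np.array(X))
            return orig_fit(self, X, y)

        monkeypatch.setattr(ev.DetectionModel, "fit", spy_fit)
        leave_one_user_out(instances, "naive_bayes", seed=0)
        rows = np.vstack([i.difference.values for i in instances])
        assert len(captured) == len(instances)
        for k, X_train in enumerate(captured):
            held_out = rows[k]
            assert not any(np.array_equal(held_out, row) for row in X_train)

    def test_deterministic_given_seed(self, instances):
        r1 = leave_one_user_out(instances, "adaboost", seed=5)
        r2 = leave_one_user_out(instances, "adaboost", seed=5)
        assert [s.score for s in r1.pooled_scores] == [s.score for s in r2.pooled_scores]


class TestAblation:
    def test_full_spec_equals_plain_loocv(self, instances):
        full = AblationSpec()
        r_ablate = run_ablation(instances, full, "adaboost", seed=1)
        r_plain = leave_one_user_out(instances, "adaboost", seed=1)
        assert [s.score for s in r_ablate.pooled_scores] == [
            s.score for s in r_plain.pooled_scores
        ]

    def test_single_device_selects_half_the_features(self, instances):
        spec = AblationSpec(devices=frozenset({Device.SMARTPHONE}))
        idx = spec.selected_indices(instances[0].difference.names)
        assert len(idx) == 114

    def test_single_family_counts(self, instances):
        names = instances[0].difference.names
        for family, count in [
            ("spectral", 48), ("statistical", 60), ("histogram", 72), ("gait", 48),
        ]:
            spec = AblationSpec(families=frozenset({family}))
            assert len(spec.selected_indices(names)) == count
            inverse = AblationSpec(families=frozenset({family}), mode="all_except")
            assert len(inverse.selected_indices(names)) == 228 - count

    def test_single_sensor_selects_half(self, instances):
        spec = AblationSpec(sensors=frozenset({Sensor.GYROSCOPE}))
        assert len(spec.selected_indices(instances[0].difference.names)) == 114

    def test_empty_selection_rejected(self, instances):
        spec = AblationSpec(mode="all_except")  # complement of everything
        with pytest.raises(ValueError, match="no features"):
            run_ablation(instances, spec, "adaboost", seed=0)

    def test_restricted_model_runs(self, instances):
        spec = AblationSpec(families=frozenset({"statistical"}))
        result = run_ablation(instances, spec, "adaboost", seed=0)
        assert 0.0 <= result.auc <= 1.0
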