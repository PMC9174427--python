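"""Leave-p-out split enumeration, per-split scoring, ROC/AUC, confusion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from s2cavd.classifier import EnsembleConfig
from s2cavd.evaluation import (
    SplitPlan,
    SplitResult,
    confusion_report,
    correlate_accuracy_calcification,
    enumerate_splits,
    roc_auc_ovr,
    run_split,
    sample_plans,
    select_final,
)
from s2cavd.s2_features import S2Record


def _cohort_frame(control=(6, 5), adenine=(4, 0), hp=(5, 4)):
    rows = []
    i = 0
    for label, (m, f) in (("Healthy", control), ("CKD", adenine), ("CKD+CAVD", hp)):
        for sex, k in (("M", m), ("F", f)):
            for _ in range(k):
                rows.append({"subject_id": f"m{i:02d}", "sex": sex, "label": label})
                i += 1
    return pd.DataFrame(rows)


class TestEnumerateSplits:
    def test_study_composition_yields_2400_plans(self):
        plans = enumerate_splits(_cohort_frame())
        assert len(plans) == 2400
        assert 6 * 5 * 4 * 5 * 4 == 2400

    def test_minimal_cohort_single_plan(self):
        plans = enumerate_splits(_cohort_frame(control=(1, 1), adenine=(1, 0), hp=(1, 1)))
        assert len(plans) == 1
        assert plans[0].train_subjects == ()

    def test_small_cohort_two_plans(self):
        plans = enumerate_splits(_cohort_frame(control=(2, 1), adenine=(1, 0), hp=(1, 1)))
        assert len(plans) == 2

    def test_insufficient_cell_named_in_error(self):
        with pytest.raises(ValueError, match=r"\(CKD, M\)"):
            enumerate_splits(_cohort_frame(adenine=(0, 0)))

    def test_plan_count_matches_binomial_product_on_random_cohorts(self):
        from math import comb
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = (int(rng.integers(1, 5)), int(rng.integers(1, 5)))
            a = (int(rng.integers(1, 4)), 0)
            h = (int(rng.integers(1, 5)), int(rng.integers(1, 5)))
            plans = enumerate_splits(_cohort_frame(c, a, h))
            expected = comb(c[0], 1) * comb(c[1], 1) * comb(a[0], 1) * comb(h[0], 1) * comb(h[1], 1)
            assert len(plans) == expected

    def test_subject_wise_integrity(self):
        for plan in enumerate_splits(_cohort_frame())[:50]:
            assert not set(plan.test_subjects) & set(plan.train_subjects)
            assert len(plan.test_subjects) == 5


class TestSelectFinal:
    def _res(self, plan_id, summed):
        return SplitResult(
            plan_id=plan_id, per_group_accuracy={}, per_group_misclassification={},
            summed_misclassification=summed, mean_test_calcification_pct=0.0,
            mean_train_calcification_pct=0.0, oob_error=0.0,
        )

    def test_argmin_of_summed_error(self):
        results = [self._res(1, 0.30), self._res(2, 0.40)]
        assert select_final(results) == 1

    def test_single_result(self):
        assert select_final([self._res(9, 0.5)]) == 9

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(1)
        results = [self._res(i, float(rng.random())) for i in range(50)]
        best = None
        for r in results:  # independent linear scan
            if best is None or r.summed_misclassification < best.summed_misclassification:
                best = r
        assert select_final(results) == best.plan_id

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_final([])


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        roc = roc_auc_ovr(scores, ["A", "A", "B", "B"], "A", ["A", "B"])
        assert roc.auc == 1.0

    def test_identical_scores_half(self):
        scores = np.full((10, 2), 0.5)
        labels = ["A"] * 5 + ["B"] * 5
        roc = roc_auc_ovr(scores, labels, "A", ["A", "B"])
        assert roc.auc == pytest.approx(0.5)

    def test_hand_case_matches_mann_whitney(self):
        s = np.array([0.9, 0.7, 0.6, 0.4, 0.35, 0.1])
        labels = ["A", "B", "A", "A", "B", "B"]
        scores = np.column_stack([s, 1 - s])
        roc = roc_auc_ovr(scores, labels, "A", ["A", "B"])
        pos = s[[l == "A" for l in labels]]
        neg = s[[l == "B" for l in labels]]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_random_scores_match_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = rng.random(40)
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            labels = ["P" if v else "N" for v in y]
            roc = roc_auc_ovr(np.column_stack([s, 1 - s]), labels, "P", ["P", "N"])
            assert roc.auc == pytest.approx(roc_auc_score(y, s))

    def test_monotone_curves_and_one_class_rejected(self):
        rng = np.random.default_rng(3)
        s = rng.random(30)
        labels = ["P" if v > 0.5 else "N" for v in rng.random(30)]
        roc = roc_auc_ovr(np.column_stack([s, 1 - s]), labels, "P", ["P", "N"])
        assert np.all(np.diff(roc.tpr_series) >= 0)
        assert np.all(np.diff(roc.fpr_series) >= 0)
        with pytest.raises(ValueError, match="positives and negatives"):
            roc_auc_ovr(np.column_stack([s, 1 - s]), ["P"] * 30, "P", ["P", "N"])


class TestConfusionReport:
    def test_printed_testing_set_shares(self):
        """251 TN, 7 FP, 11 FN, 283 TP over 552 sounds reproduce the
        printed true-negative / false-positive / false-negative shares."""
        pred, true = [], []
        pred += ["Healthy"] * 251; true += ["Healthy"] * 251
        pred += ["CKD"] * 7; true += ["Healthy"] * 7
        pred += ["Healthy"] * 11; true += ["CKD+CAVD"] * 11
        pred += ["CKD+CAVD"] * 283; true += ["CKD+CAVD"] * 283
        rep = confusion_report(pred, true)
        assert rep.binarized_shares_pct["TN"] == pytest.approx(45.47, abs=0.005)
        assert rep.binarized_shares_pct["FP"] == pytest.approx(1.27, abs=0.005)
        assert rep.binarized_shares_pct["FN"] == pytest.approx(1.99, abs=0.005)
        assert rep.binarized_shares_pct["TP"] == pytest.approx(51.27, abs=0.005)
        assert sum(rep.binarized_counts.values()) == 552
        assert sum(rep.binarized_shares_pct.values()) == pytest.approx(100.0)

    def test_all_correct_identity(self):
        labels = ["Healthy"] * 3 + ["CKD"] * 3 + ["CKD+CAVD"] * 3
        rep = confusion_report(labels, labels)
        assert np.allclose(np.diag(rep.matrix_pct), 100.0)
        assert rep.ppv_ckd == 100.0 and rep.ppv_cavd == 100.0 and rep.npv_healthy == 100.0

    def test_two_by_two_hand_case(self):
        pred = ["Healthy", "Healthy", "CKD", "CKD", "CKD"]
        true = ["Healthy", "CKD", "CKD", "CKD", "Healthy"]
        rep = confusion_report(pred, true)
        assert rep.npv_healthy == pytest.approx(100 * 1 / 2)
        assert rep.ppv_ckd == pytest.approx(100 * 2 / 3)
        rows = rep.matrix_pct.sum(axis=1)
        assert np.allclose(rows[rows > 0], 100.0, atol=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_report([], [])


class TestCorrelation:
    def _res(self, i, calc, acc):
        return SplitResult(
            plan_id=i, per_group_accuracy={"CKD+CAVD": acc},
            per_group_misclassification={}, summed_misclassification=0.0,
            mean_test_calcification_pct=calc, mean_train_calcification_pct=-calc,
            oob_error=0.0,
        )

    def test_exact_linear(self):
        res = [self._res(i, float(i), 0.1 * i) for i in range(5)]
        assert correlate_accuracy_calcification(res, "test").r == pytest.approx(1.0)
        assert correlate_accuracy_calcification(res, "train").r == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        res = [self._res(i, float(rng.random()), float(rng.random())) for i in range(30)]
        got = correlate_accuracy_calcification(res, "test").r
        x = np.array([r.mean_test_calcification_pct for r in res])
        y = np.array([r.per_group_accuracy["CKD+CAVD"] for r in res])
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_series_rejected(self):
        res = [self._res(i, 1.0, 0.5) for i in range(5)]
        with pytest.raises(ValueError, match="constant"):
            correlate_accuracy_calcification(res, "test")


class TestRunSplit:
    def test_determinism_and_integrity(self, cohort_dataset):
        cohort, records, calcification = cohort_dataset
        from s2cavd.workbench import subjects_to_frame
        frame = subjects_to_frame(cohort)
        plan = enumerate_splits(frame)[0]
        cfg = EnsembleConfig(seed=5)
        a = run_split(records, calcification, plan, cfg)
        b = run_split(records, calcification, plan, cfg)
        assert a.per_group_accuracy == b.per_group_accuracy
        assert a.summed_misclassification == b.summed_misclassification

    def test_shuffled_labels_give_chance_accuracy(self, cohort_dataset):
        cohort, records, calcification = cohort_dataset
        from s2cavd.workbench import subjects_to_frame
        rng = np.random.default_rng(6)
        labels = [r.label for r in records]
        rng.shuffle(labels)
        shuffled = [
            S2Record(waveform=r.waveform, subject_id=r.subject_id,
                     session_id=r.session_id, label=l)
            for r, l in zip(records, labels)
        ]
        plan = enumerate_splits(subjects_to_frame(cohort))[100]
        res = run_split(shuffled, calcification, plan, EnsembleConfig(seed=6))
        accs = [a for a in res.per_group_accuracy.values() if not np.isnan(a)]
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.15)


def test_sample_plans_seeded_and_bounded():
    plans = enumerate_splits(_cohort_frame())
    a = sample_plans(plans, 20, seed=3)
    b = sample_plans(plans, 20, seed=3)
    assert [p.plan_id for p in a] == [p.plan_id for p in b]
    assert len(a) == 20
    assert sample_plans(plans[:5], 20, seed=3) == plans[:5]
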