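"""Subject-wise leave-p-out evaluation of the S2 classifier.

Every admissible test set matches a fixed (group, sex) composition —
1M + 1F Healthy, 1M CKD, 1M + 1F CKD+CAVD — and all of a subject's sounds
stay on one side of the split, the guard against identity confounding.
For each split plan the feature space is refitted on the training subjects
only, the ensemble retrained, and every test sound classified; per-group
accuracy, one-vs-rest ROC/AUC, a predicted-by-true confusion report with
predictive values, and the correlation between accuracy and mean
calcification burden are derived from the sweep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CLASS_ORDER, EnsembleConfig, predict_batch, train_forest
from .s2_features import S2Record, fit_feature_space, project_batch

#: Test-set composition: (label, sex) -> number of test subjects.
DEFAULT_TEST_PATTERN: Dict[Tuple[str, str], int] = {
    ("Healthy", "M"): 1,
    ("Healthy", "F"): 1,
    ("CKD", "M"): 1,
    ("CKD+CAVD", "M"): 1,
    ("CKD+CAVD", "F"): 1,
}

DISEASED = ("CKD", "CKD+CAVD")


@dataclass(frozen=True)
class SplitPlan:
    plan_id: int
    test_subjects: Tuple[str, ...]
    train_subjects: Tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.test_subjects) & set(self.train_subjects):
            raise ValueError("test and train subject sets overlap")


@dataclass
class SplitResult:
    plan_id: int
    per_group_accuracy: Dict[str, float]
    per_group_misclassification: Dict[str, float]
    summed_misclassification: float
    mean_test_calcification_pct: float
    mean_train_calcification_pct: float
    oob_error: float
    test_true_labels: Optional[List[str]] = None
    test_vote_fractions: Optional[np.ndarray] = None
    classes: Optional[Tuple[str, ...]] = None


@dataclass
class ROCCurve:
    class_label: str
    thresholds: np.ndarray
    fpr_series: np.ndarray
    tpr_series: np.ndarray
    auc: float


@dataclass
class ConfusionReport:
    classes: Tuple[str, ...]
    matrix_pct: np.ndarray          # rows: predicted, cols: true; rows sum to 100
    counts: np.ndarray
    ppv_ckd: float
    ppv_cavd: float
    npv_healthy: float
    binarized_counts: Dict[str, int]      # TP/TN/FP/FN, positive = diseased
    binarized_shares_pct: Dict[str, float]


@dataclass
class CorrelationResult:
    r: float
    n: int
    side: str


def enumerate_splits(
    cohort: pd.DataFrame,
    test_pattern: Optional[Mapping[Tuple[str, str], int]] = None,
) -> List[SplitPlan]:
    """Enumerate every test set matching the required (group, sex) pattern.

    ``cohort`` needs columns ``subject_id``, ``sex``, ``label``.  The plan
    count equals the product of per-cell binomial coefficients; ordering is
    deterministic (subjects sorted within each cell, cells in fixed order).
    """
    pattern = dict(test_pattern) if test_pattern is not None else dict(DEFAULT_TEST_PATTERN)
    cells: List[List[Tuple[str, ...]]] = []
    for (label, sex), k in pattern.items():
        members = sorted(
            cohort.loc[(cohort["label"] == label) & (cohort["sex"] == sex), "subject_id"]
        )
        if len(members) < k:
            raise ValueError(
                f"cohort has {len(members)} subjects in cell ({label}, {sex}), need {k}"
            )
        cells.append([tuple(c) for c in itertools.combinations(members, k)])
    all_ids = sorted(cohort["subject_id"])
    plans: List[SplitPlan] = []
    for plan_id, combo in enumerate(itertools.product(*cells)):
        test = tuple(s for cell in combo for s in cell)
        train = tuple(s for s in all_ids if s not in set(test))
        plans.append(SplitPlan(plan_id=plan_id, test_subjects=test, train_subjects=train))
    return plans


def run_split(
    records: Sequence[S2Record],
    calcification: Mapping[str, float],
    plan: SplitPlan,
    config: Optional[EnsembleConfig] = None,
    variance_threshold: float = 0.05,
    keep_predictions: bool = False,
) -> SplitResult:
    """Train on the plan's training subjects and score every test sound.

    The feature space is fitted on training-subject sounds only; test
    sounds are projected onto it (never refitted), classified, and per-group
    accuracy over sounds plus the summed misclassification across groups is
    reported.  Mean calcification burden of CKD+CAVD mice is recorded for
    both sides.
    """
    test_set, train_set = set(plan.test_subjects), set(plan.train_subjects)
    train_records = [r for r in records if r.subject_id in train_set]
    test_records = [r for r in records if r.subject_id in test_set]
    assert not {r.subject_id for r in train_records} & {r.subject_id for r in test_records}
    groups_in_test = {r.label for r in test_records}
    for g in CLASS_ORDER:
        if g not in groups_in_test:
            raise ValueError(f"test set has zero sounds for group {g}")

    space = fit_feature_space(train_records, variance_threshold)
    train_feats = project_batch(train_records, space)
    test_feats = project_batch(test_records, space)
    ensemble = train_forest(train_feats, config)
    preds = predict_batch(ensemble, test_feats)

    acc: Dict[str, float] = {}
    for g in CLASS_ORDER:
        sel = [p.label == g for p, r in zip(preds, test_records) if r.label == g]
        acc[g] = float(np.mean(sel)) if sel else float("nan")
    mis = {g: 1.0 - a for g, a in acc.items()}

    def _side_calc(ids: Iterable[str]) -> float:
        vals = [calcification[s] for s in ids if calcification.get(s, 0.0) > 0]
        return float(np.mean(vals)) if vals else 0.0

    result = SplitResult(
        plan_id=plan.plan_id,
        per_group_accuracy=acc,
        per_group_misclassification=mis,
        summed_misclassification=float(sum(mis.values())),
        mean_test_calcification_pct=_side_calc(plan.test_subjects),
        mean_train_calcification_pct=_side_calc(plan.train_subjects),
        oob_error=ensemble.oob_error,
    )
    if keep_predictions:
        result.test_true_labels = [r.label for r in test_records]
        result.test_vote_fractions = np.stack([p.vote_fractions for p in preds])
        result.classes = ensemble.classes
    return result


def select_final(results: Sequence[SplitResult]) -> int:
    """Plan id with the lowest summed misclassification (ties: lowest id)."""
    if not results:
        raise ValueError("no split results")
    best = min(results, key=lambda r: (r.summed_misclassification, r.plan_id))
    return best.plan_id


def roc_auc_ovr(
    scores: np.ndarray,
    true_labels: Sequence[str],
    class_label: str,
    classes: Sequence[str],
) -> ROCCurve:
    """One-vs-rest ROC for one class using its vote fraction as the score.

    Sweeps a threshold over the class's vote fractions and integrates by
    the trapezoid rule; this equals the normalized Mann-Whitney statistic.
    """
    classes = list(classes)
    col = classes.index(class_label)
    s = np.asarray(scores, dtype=float)[:, col]
    y = np.asarray([t == class_label for t in true_labels], dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"ROC undefined: class {class_label} needs both positives and negatives")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # collapse ties: keep the last point of each distinct score
    distinct = np.concatenate((s_sorted[1:] != s_sorted[:-1], [True]))
    tpr = np.concatenate(([0.0], tps[distinct] / n_pos))
    fpr = np.concatenate(([0.0], fps[distinct] / n_neg))
    thresholds = np.concatenate(([np.inf], s_sorted[distinct]))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(class_label=class_label, thresholds=thresholds, fpr_series=fpr,
                    tpr_series=tpr, auc=auc)


def confusion_report(
    pred_labels: Sequence[str], true_labels: Sequence[str], classes: Sequence[str] = CLASS_ORDER
) -> ConfusionReport:
    """Row-normalized predicted-by-true confusion with predictive values.

    PPV for each disease class = correct predictions of that class over all
    predictions of that class; NPV = correct Healthy predictions over all
    Healthy predictions.  TP/TN/FP/FN use the disease binarization
    (positive = CKD or CKD+CAVD) with shares of the total sound count.
    """
    if len(pred_labels) != len(true_labels):
        raise ValueError("prediction and truth lengths differ")
    if len(pred_labels) == 0:
        raise ValueError("empty prediction set")
    classes = tuple(classes)
    k = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(pred_labels, true_labels):
        counts[k[p], k[t]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        matrix_pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)

    def _ppv(c: str) -> float:
        i = k[c]
        denom = counts[i].sum()
        return float(100.0 * counts[i, i] / denom) if denom else float("nan")

    pred_pos = np.array([p in DISEASED for p in pred_labels])
    true_pos = np.array([t in DISEASED for t in true_labels])
    tp = int(np.sum(pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    total = len(pred_labels)
    bc = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    shares = {kk: 100.0 * v / total for kk, v in bc.items()}
    return ConfusionReport(
        classes=classes,
        matrix_pct=matrix_pct,
        counts=counts,
        ppv_ckd=_ppv("CKD"),
        ppv_cavd=_ppv("CKD+CAVD"),
        npv_healthy=_ppv("Healthy"),
        binarized_counts=bc,
        binarized_shares_pct=shares,
    )


def correlate_accuracy_calcification(
    results: Sequence[SplitResult], side: str = "test"
) -> CorrelationResult:
    """Pearson r between CKD+CAVD accuracy and mean calcification per plan."""
    if side not in ("train", "test"):
        raise ValueError("side must be 'train' or 'test'")
    attr = f"mean_{side}_calcification_pct"
    xs = np.array([getattr(r, attr) for r in results])
    ys = np.array([r.per_group_accuracy["CKD+CAVD"] for r in results])
    if len(xs) < 3:
        raise ValueError("need >= 3 split results for a correlation")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined for a constant series")
    r, _ = stats.pearsonr(xs, ys)
    return CorrelationResult(r=float(r), n=len(xs), side=side)


def sample_plans(
    plans: Sequence[SplitPlan], n: int, seed: int
) -> List[SplitPlan]:
    """Seeded random subsample of split plans (without replacement)."""
    if n >= len(plans):
        return list(plans)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    idx = rng.choice(len(plans), size=n, replace=False)
    return [plans[i] for i in np.sort(idx)]


def plan_seed(global_seed: int, plan_id: int) -> int:
    """Deterministic per-plan seed derived from (global seed, plan id)."""
    return (global_seed * 1_000_003 + plan_id * 7919 + 17) % (2**31 - 1)
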