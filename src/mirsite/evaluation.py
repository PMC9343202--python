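"""Evaluation: confusion metrics, PR/ROC curves, 5-fold CV, t-tests.

Headline numbers are means over stratified 5-fold cross-validation: each
fold's model is trained from fresh initialization on the other four folds
and evaluated on the held-out fold; fold metrics are averaged unweighted.
Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP) (the standard
definitions).  AP uses step-wise interpolation; AUC equals the
Mann-Whitney probability P(score_pos > score_neg) + half the tie mass.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from mirsite.sequence_io import SiteDataset
from mirsite.training import TrainConfig, encode_dataset, train_model

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """True/false positive/negative counts of a thresholded classifier."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    """Metrics of one evaluation (optionally aggregating per-fold reports).

    Metric values are fractions in [0, 1]; an undefined ratio (zero
    denominator) is reported as NaN and excluded from cross-fold means.
    """

    counts: ConfusionCounts
    acc: float
    sens: float
    spec: float
    f_measure: float
    ap: float
    auc: float
    threshold: float = 0.5
    per_fold: list["EvalReport"] | None = None
    p_value_vs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "counts": {"TP": self.counts.TP, "FP": self.counts.FP,
                       "TN": self.counts.TN, "FN": self.counts.FN},
            "acc": self.acc, "sens": self.sens, "spec": self.spec,
            "f_measure": self.f_measure, "ap": self.ap, "auc": self.auc,
            "threshold": self.threshold,
        }
        if self.per_fold is not None:
            d["per_fold"] = [r.to_dict() for r in self.per_fold]
        if self.p_value_vs:
            d["p_value_vs"] = self.p_value_vs
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN, predicting positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, F-measure) from counts.

    acc = (TP+TN)/total, sens = TP/(TP+FN), spec = TN/(TN+FP),
    F = 2TP/(2TP+FP+FN).  A zero denominator yields NaN.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics of an empty evaluation")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    acc = (counts.TP + counts.TN) / counts.total
    sens = ratio(counts.TP, counts.TP + counts.FN)
    spec = ratio(counts.TN, counts.TN + counts.FP)
    f = ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN)
    return acc, sens, spec, f


def pr_curve_and_ap(scores, labels):
    """Precision-recall curve and step-interpolated average precision.

    Thresholds sweep the distinct scores descending;
    AP = sum_i (R_i - R_{i-1}) * P_i.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("average precision needs at least one positive label")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # sklearn returns the curve in increasing-threshold order with a final
    # (P=1, R=0) sentinel; AP below is the step-wise sum over the sweep.
    ap = float(-np.sum(np.diff(recall) * precision[:-1]))
    return (precision, recall, thresholds), ap


def roc_curve_and_auc(scores, labels):
    """ROC curve and trapezoidal AUC (= the Mann-Whitney statistic)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thresholds), auc


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report (confusion metrics + AP + AUC) for one score vector."""
    counts = confusion(scores, labels, threshold)
    acc, sens, spec, f = metrics(counts)
    _, ap = pr_curve_and_ap(scores, labels)
    _, auc = roc_curve_and_auc(scores, labels)
    return EvalReport(counts=counts, acc=acc, sens=sens, spec=spec,
                      f_measure=f, ap=ap, auc=auc, threshold=threshold)


def stratified_kfold(dataset: SiteDataset, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign each pair to one of k stratified folds, deterministically.

    Folds are disjoint, cover the dataset, and per-fold class counts are
    within one of perfect proportion.  Requires at least k members per class.
    """
    labels = dataset.labels
    for cls in (0, 1):
        if int(np.sum(labels == cls)) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            fold_of[dataset.pairs[i].pair_id] = fold
    return fold_of


def _mean_report(fold_reports: list[EvalReport]) -> EvalReport:
    """Unweighted mean of fold metrics; counts are summed; NaNs excluded."""

    def mean_of(attr):
        vals = [getattr(r, attr) for r in fold_reports]
        vals = [v for v in vals if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else float("nan")

    counts = ConfusionCounts(
        TP=sum(r.counts.TP for r in fold_reports),
        FP=sum(r.counts.FP for r in fold_reports),
        TN=sum(r.counts.TN for r in fold_reports),
        FN=sum(r.counts.FN for r in fold_reports),
    )
    return EvalReport(
        counts=counts,
        acc=mean_of("acc"), sens=mean_of("sens"), spec=mean_of("spec"),
        f_measure=mean_of("f_measure"), ap=mean_of("ap"), auc=mean_of("auc"),
        threshold=fold_reports[0].threshold,
        per_fold=fold_reports,
    )


def cross_validate(
    dataset: SiteDataset,
    model_ctor,
    tables,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[list[EvalReport], EvalReport]:
    """Stratified k-fold cross-validation of a classifier.

    One model per fold, trained from fresh (fold-seeded) initialization on
    the other folds.  Returns (fold reports, mean report); the mean report
    carries the fold reports in ``per_fold``.
    """
    fold_of = stratified_kfold(dataset, k=k, seed=seed)
    dataset.fold_of = fold_of
    fold_reports: list[EvalReport] = []
    for fold in range(k):
        train_pairs = [p for p in dataset.pairs if fold_of[p.pair_id] != fold]
        test_pairs = [p for p in dataset.pairs if fold_of[p.pair_id] == fold]
        train_ds = SiteDataset(pairs=train_pairs)
        test_ds = SiteDataset(pairs=test_pairs)
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))
        fold_config = TrainConfig(**{**train_config.__dict__, "seed": fold_seed})
        model = model_ctor(tables[0].dim, fold_seed)
        model, _ = train_model(train_ds, model, tables, fold_config)
        X_m, X_c, y = encode_dataset(test_ds, tables[0], tables[1])
        scores = model.predict_proba(X_m, X_c)[:, 1]
        fold_reports.append(evaluate_scores(scores, y, threshold))
        logger.info("fold %d/%d acc %.4f", fold + 1, k, fold_reports[-1].acc)
    return fold_reports, _mean_report(fold_reports)


def students_t_test(
    fold_scores_a, fold_scores_b, paired: bool = True
) -> tuple[float, float]:
    """Student's t-test between two methods' per-fold scores.

    Paired by default: both methods evaluated on identical folds, t computed
    on the differences with n-1 degrees of freedom, two-sided p.  If the
    differences have zero variance the p-value degenerates: 0 when the means
    differ, 1 when they are equal (with a warning).
    """
    a = np.asarray(fold_scores_a, dtype=np.float64)
    b = np.asarray(fold_scores_b, dtype=np.float64)
    if paired and a.shape != b.shape:
        raise ValueError("paired test needs equal-length score lists")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two scores per method")
    if paired:
        diff = a - b
        if np.allclose(diff, diff[0], rtol=1e-12, atol=1e-12):
            warnings.warn("zero variance of paired differences; degenerate p-value")
            return (float("inf") if diff[0] != 0 else 0.0,
                    0.0 if diff[0] != 0 else 1.0)
        t, p = stats.ttest_rel(a, b)
    else:
        if np.all(a == a[0]) and np.all(b == b[0]):
            warnings.warn("zero variance in both samples; degenerate p-value")
            return (float("inf") if a[0] != b[0] else 0.0,
                    0.0 if a[0] != b[0] else 1.0)
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def write_curve_tsv(path, columns: dict[str, np.ndarray]) -> None:
    """Write named curve columns (e.g. threshold/precision/recall) as TSV."""
    names = list(columns)
    arrays = [np.asarray(columns[n], dtype=np.float64) for n in names]
    n = max(len(a) for a in arrays)
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(
                f"{a[i]:.17g}" if i < len(a) else "" for a in arrays) + "\n")
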