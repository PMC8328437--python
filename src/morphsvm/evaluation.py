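"""Replicated k-fold cross-validation, confusion-matrix metrics, macro ROC.

Conventions:

* Confusion matrices have rows = true labels, columns = predicted labels,
  in a fixed sorted class order.
* Per-class precision/recall/F1 come from the one-vs-rest collapse of the
  confusion matrix; "overall" values are unweighted (macro) means across
  classes, with undefined entries (zero denominator) reported as NaN and
  excluded from the mean with a warning. Accuracy is the main-diagonal
  proportion, reported separately.
* One replicate of k-fold CV sums the k fold confusion matrices into one
  matrix and computes metrics from that sum; replicate means and standard
  deviations summarize the replicates.
* Augmentation, when requested, is applied inside the CV loop to the
  training folds only — synthetic copies never reach a held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .augment import AugmentSpec, augment_dataset, conform_to_spec
from .dataset import LabeledImageSet
from .svm import PairwiseLinearSVM


class EvaluationError(ValueError):
    pass


def kfold_split(
    labels, k: int, seed: int | None = None, stratified: bool = True
) -> list[np.ndarray]:
    """Partition sample indices into k disjoint folds.

    Stratified mode keeps per-fold class proportions within one sample of
    the overall proportions; falls back to a plain random split (with a
    warning) when a class has fewer than k samples.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2 or k > n:
        raise EvaluationError(f"k must be in [2, n_samples={n}], got {k}")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            warnings.warn(
                f"smallest class has {counts.min()} < k={k} samples; "
                "falling back to non-stratified folds",
                stacklevel=2,
            )
            stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), labels)]


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Count matrix with rows = true, columns = predicted, in *classes* order."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def binary_tallies(cm: np.ndarray) -> dict[str, np.ndarray]:
    """One-vs-rest TP/FP/FN/TN per class from a confusion matrix."""
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def macro_average(values: np.ndarray) -> float:
    """Unweighted mean across classes, excluding NaN (undefined) entries."""
    values = np.asarray(values, dtype=np.float64)
    if np.isnan(values).any():
        warnings.warn(
            "undefined per-class metric excluded from the macro average",
            stacklevel=2,
        )
    if np.isnan(values).all():
        return float("nan")
    return float(np.nanmean(values))


@dataclass
class MetricsReport:
    """Confusion matrix plus the derived per-class and macro metrics."""

    classes: list
    confusion: np.ndarray
    precision: np.ndarray  # per class, NaN when the predicted column is empty
    recall: np.ndarray     # per class, NaN when the true row is empty
    f1: np.ndarray
    accuracy: float
    overall_precision: float
    overall_recall: float
    overall_f1: float


def metrics_from_confusion(cm: np.ndarray, classes) -> MetricsReport:
    """Accuracy (diagonal proportion), per-class precision/recall/F1 and
    their unweighted macro means."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise EvaluationError(f"invalid confusion matrix of shape {cm.shape}")
    t = binary_tallies(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(t["TP"] + t["FP"] > 0,
                             t["TP"] / np.maximum(t["TP"] + t["FP"], 1), np.nan)
        recall = np.where(t["TP"] + t["FN"] > 0,
                          t["TP"] / np.maximum(t["TP"] + t["FN"], 1), np.nan)
        denom = precision + recall
        f1 = np.where(np.nan_to_num(denom) > 0, 2 * precision * recall / denom, np.nan)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # one consolidated warning below
        op, orr, of1 = (macro_average(precision), macro_average(recall),
                        macro_average(f1))
    if np.isnan(precision).any() or np.isnan(recall).any() or np.isnan(f1).any():
        warnings.warn(
            "some per-class metrics were undefined (empty row/column) and "
            "were excluded from the macro averages",
            stacklevel=2,
        )
    return MetricsReport(
        classes=list(classes), confusion=cm,
        precision=precision, recall=recall, f1=f1,
        accuracy=accuracy,
        overall_precision=op, overall_recall=orr, overall_f1=of1,
    )


@dataclass
class CVResult:
    """Per-replicate reports and their across-replicate summary."""

    replicates: list[MetricsReport]
    classes: list

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.replicates]))

    @property
    def sd_accuracy(self) -> float:
        a = [r.accuracy for r in self.replicates]
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    def summary(self) -> dict:
        out = {"n_replicates": len(self.replicates)}
        for attr in ("accuracy", "overall_precision", "overall_recall", "overall_f1"):
            vals = np.array([getattr(r, attr) for r in self.replicates])
            out[f"{attr}_mean"] = float(np.nanmean(vals))
            out[f"{attr}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        return out


def cross_validate(
    dataset: LabeledImageSet,
    feature_fn,
    k: int = 10,
    replicates: int = 20,
    seed: int = 0,
    augment_spec: AugmentSpec | None = None,
    stratified: bool = True,
    svm_c: float = 1.0,
    standardize: bool = False,
) -> CVResult:
    """Replicated k-fold cross-validation of the full pipeline.

    feature_fn : callable mapping a list of images to an (n, d) matrix.
    augment_spec : optional training-fold augmentation; the held-out fold
        is only geometry-conformed (center crop), never expanded.

    Each replicate draws a fresh fold assignment; its k fold confusion
    matrices are summed and the metrics of the summed matrix reported.
    """
    counts = dataset.class_counts()
    if min(counts.values()) < 2:
        raise EvaluationError("every class needs at least 2 samples for CV")
    classes = dataset.classes
    labels = np.asarray(dataset.labels)
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        folds = kfold_split(labels, k, seed=rep_seed, stratified=stratified)
        cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for fold_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)
            train = dataset.subset(train_idx)
            test = dataset.subset(test_idx)
            if augment_spec is not None:
                fold_spec = replace(
                    augment_spec, seed=int(rng.integers(0, 2**31 - 1))
                )
                train = augment_dataset(train, fold_spec)
                test = conform_to_spec(test, fold_spec)
            Xtr = feature_fn(train.images)
            Xte = feature_fn(test.images)
            clf = PairwiseLinearSVM(
                C=svm_c, standardize=standardize, fit_posterior=False
            )
            clf.fit(Xtr, np.asarray(train.labels))
            pred = clf.predict(Xte)
            cm += confusion_matrix(test.labels, pred, classes)
        reports.append(metrics_from_confusion(cm, classes))
    return CVResult(replicates=reports, classes=classes)


@dataclass
class ROCResult:
    """Per-class one-vs-rest ROC curves plus their macro average."""

    classes: list
    fpr: dict          # class -> FPR breakpoints
    tpr: dict          # class -> TPR values
    auc_per_class: dict
    macro_fpr: np.ndarray
    macro_tpr: np.ndarray
    macro_auc: float


def roc_macro(y_true, posteriors: np.ndarray, classes) -> ROCResult:
    """Macro-averaged one-vs-rest ROC from posterior probability vectors.

    Per class: sweep thresholds over that class's posterior column
    (one-vs-rest). The macro curve averages the per-class TPRs linearly
    interpolated on the union of all FPR breakpoints; AUC is trapezoidal.
    Classes absent from the truth are skipped with a warning.
    """
    classes = list(classes)
    y_true = np.asarray(y_true)
    posteriors = np.asarray(posteriors, dtype=np.float64)
    if posteriors.shape != (len(y_true), len(classes)):
        raise EvaluationError(
            f"posteriors shape {posteriors.shape} != (n_samples, n_classes)"
        )
    present = set(y_true.tolist())
    if len(present) < 2:
        raise EvaluationError("ROC needs at least 2 classes present in the truth")
    fpr_d, tpr_d, auc_d = {}, {}, {}
    for ci, c in enumerate(classes):
        if c not in present:
            warnings.warn(f"class '{c}' absent from the truth; skipped in ROC",
                          stacklevel=2)
            continue
        y_bin = (y_true == c).astype(int)
        if y_bin.all():
            warnings.warn(f"class '{c}' has no negatives; skipped in ROC",
                          stacklevel=2)
            continue
        fpr, tpr, _ = _sk_roc_curve(y_bin, posteriors[:, ci])
        fpr_d[c], tpr_d[c] = fpr, tpr
        auc_d[c] = float(np.trapezoid(tpr, fpr))
    grid = np.unique(np.concatenate([fpr_d[c] for c in fpr_d]))
    macro_tpr = np.mean(
        [np.interp(grid, fpr_d[c], tpr_d[c]) for c in fpr_d], axis=0
    )
    macro_auc = float(np.trapezoid(macro_tpr, grid))
    return ROCResult(
        classes=classes, fpr=fpr_d, tpr=tpr_d, auc_per_class=auc_d,
        macro_fpr=grid, macro_tpr=macro_tpr, macro_auc=macro_auc,
    )


def roc_experiment(
    dataset: LabeledImageSet,
    feature_fn,
    seed: int = 0,
    augment_spec: AugmentSpec | None = None,
    svm_c: float = 1.0,
) -> ROCResult:
    """Halve the samples, augment+train on one half, score the other.

    Mirrors the ROC protocol: a 50/50 random split, training-half
    augmentation, Platt-calibrated posteriors on the test half.
    """
    rng = np.random.default_rng(seed)
    n = len(dataset)
    perm = rng.permutation(n)
    half = n // 2
    train = dataset.subset(perm[:half])
    test = dataset.subset(perm[half:])
    if augment_spec is not None:
        fold_spec = replace(augment_spec, seed=int(rng.integers(0, 2**31 - 1)))
        train = augment_dataset(train, fold_spec)
        test = conform_to_spec(test, fold_spec)
    clf = PairwiseLinearSVM(C=svm_c, fit_posterior=True)
    clf.fit(feature_fn(train.images), np.asarray(train.labels))
    post = clf.predict_proba(feature_fn(test.images))
    return roc_macro(np.asarray(test.labels), post, clf.classes_.tolist())
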