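"""Experiment harness: splits, metrics, cross-validation, PCA baseline,
runtime profiling, and the original-vs-transfer ablation comparison.

Splits and folds are stratified by class.  Metrics follow the standard
definitions (precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean) with macro averages as unweighted means over classes;
undefined per-class values are reported as 0 with a warning.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import SegmentDataset, label_from_code
from .features import RFGRConfig, generate_transfer_features
from .models import ClassifierSpec, FittedClassifier, fit_spec, predict


class StratificationError(ValueError):
    """A class has too few rows to stratify the requested split/folds."""


@dataclass
class EvaluationReport:
    """Accuracy, per-class metrics, macro averages, and confusion matrix."""

    accuracy: float
    per_class: dict[int, dict[str, float]]  # code -> precision/recall/f1
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # rows = true, columns = predicted
    class_codes: list[int]
    runtime_seconds: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Table in the precision/recall/F1-per-class + Average layout."""
        rows = []
        for code in self.class_codes:
            m = self.per_class[code]
            rows.append(
                {
                    "target class": label_from_code(code).name,
                    "precision": m["precision"],
                    "recall": m["recall"],
                    "f1": m["f1"],
                }
            )
        rows.append(
            {
                "target class": "Average",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            }
        )
        return pd.DataFrame(rows)

    def confusion_frame(self) -> pd.DataFrame:
        names = [label_from_code(c).name for c in self.class_codes]
        return pd.DataFrame(self.confusion, index=names, columns=names)


@dataclass
class CVReport:
    """k-fold cross-validation accuracies with mean and standard deviation."""

    k: int
    fold_accuracies: list[float]
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        self.mean = float(acc.mean())
        self.std = float(acc.std())  # population std over the k folds


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_indices(
    y: np.ndarray, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified disjoint-exhaustive index split."""
    y = np.asarray(y)
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    if train_fraction == 1.0:
        return np.arange(len(y)), np.empty(0, dtype=int)
    codes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise StratificationError(
            f"class {codes[counts.argmin()]} has fewer than 2 rows"
        )
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(idx_train), np.sort(idx_test)


def stratified_split(
    dataset: SegmentDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SegmentDataset, SegmentDataset]:
    """Per-class proportions preserved within rounding; disjoint, exhaustive."""
    idx_train, idx_test = split_indices(dataset.y, train_fraction, seed)
    return dataset.subset(idx_train), dataset.subset(idx_test)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_classifier(
    fitted: FittedClassifier, test_features: np.ndarray, test_labels
) -> EvaluationReport:
    """Score a fitted model on held-out rows."""
    y_true = np.asarray(test_labels)
    if len(y_true) == 0:
        raise ValueError("test set is empty")
    t0 = time.perf_counter()
    y_pred = predict(fitted, test_features)
    runtime = time.perf_counter() - t0
    if y_pred.shape[0] != y_true.shape[0]:
        raise ValueError("features and labels disagree on row count")
    codes = sorted(int(c) for c in np.union1d(y_true, fitted.classes_))
    missing = sorted(set(codes) - set(int(c) for c in np.unique(y_true)))
    if missing:
        warnings.warn(
            f"classes {missing} absent from the test truth; their "
            "precision/recall are reported as 0",
            stacklevel=2,
        )
    return report_from_predictions(y_true, y_pred, codes, runtime)


def report_from_predictions(
    y_true, y_pred, class_codes=None, runtime_seconds: float = 0.0
) -> EvaluationReport:
    """Build the full report from truth/prediction code sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if class_codes is None:
        class_codes = sorted(int(c) for c in np.union1d(y_true, y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division handled via zero_division=0
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=class_codes, zero_division=0
        )
    cm = confusion_matrix(y_true, y_pred, labels=class_codes)
    per_class = {
        int(c): {"precision": float(p), "recall": float(r), "f1": float(f)}
        for c, p, r, f in zip(class_codes, prec, rec, f1)
    }
    return EvaluationReport(
        accuracy=float(np.trace(cm) / cm.sum()),
        per_class=per_class,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=cm,
        class_codes=[int(c) for c in class_codes],
        runtime_seconds=runtime_seconds,
    )


# ---------------------------------------------------------------------------
# Feature construction shared by CV / ablation
# ---------------------------------------------------------------------------

def build_features(
    train: SegmentDataset,
    test: SegmentDataset,
    mode: str,
    config: RFGRConfig,
    n_components: int = 20,
):
    """(train X, test X) under a feature mode: original / pca / transfer."""
    if mode == "original":
        return train.X, test.X
    if mode == "pca":
        tr, te, _ = pca_baseline(train.X, test.X, n_components)
        return tr, te
    if mode == "transfer":
        train_fs, test_fs, _ = generate_transfer_features(train, test, config)
        return train_fs.X, test_fs.X
    raise ValueError(f"unknown feature mode {mode!r}")


def kfold_cv(
    dataset: SegmentDataset,
    spec: ClassifierSpec,
    feature_mode: str = "transfer",
    k: int = 10,
    config: RFGRConfig | None = None,
) -> CVReport:
    """Stratified k-fold accuracy; transfer extractors are refit per fold.

    Inside every fold the feature-construction stage sees only that
    fold's training portion, so held-out rows never inform the features
    that score them.
    """
    config = config or RFGRConfig()
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    codes, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"class {codes[counts.argmin()]} has fewer than k={k} rows"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    accs = []
    for idx_train, idx_test in cv.split(dataset.X, dataset.y):
        train, test = dataset.subset(idx_train), dataset.subset(idx_test)
        Xtr, Xte = build_features(train, test, feature_mode, config)
        fitted = fit_spec(spec, Xtr, train.y)
        accs.append(float((predict(fitted, Xte) == test.y).mean()))
    return CVReport(k=k, fold_accuracies=accs)


def pca_baseline(
    train: np.ndarray, test: np.ndarray, n_components: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto the leading principal components fitted on train only."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if n_components > train.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds feature width {train.shape[1]}"
        )
    pca = PCA(n_components=n_components, random_state=0)
    reduced_train = pca.fit_transform(train)
    reduced_test = (
        pca.transform(test) if test.shape[0] else np.empty((0, n_components))
    )
    return reduced_train, reduced_test, pca.explained_variance_ratio_


def runtime_profile(stage, *args, **kwargs) -> tuple[object, float]:
    """Wall-clock a callable; returns (result, seconds).

    Runtime is reported for orientation only — it is hardware-dependent
    and never part of a scientific claim.
    """
    t0 = time.perf_counter()
    result = stage(*args, **kwargs)
    return result, time.perf_counter() - t0


def ablation_table(
    dataset: SegmentDataset,
    spec: ClassifierSpec,
    config: RFGRConfig | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, EvaluationReport]]:
    """Original vs transfer features under one identical split and seed.

    Returns the side-by-side accuracy + per-class-F1 table and the two
    underlying reports keyed by feature set.
    """
    config = config or RFGRConfig(seed=seed)
    train, test = stratified_split(dataset, train_fraction, seed)
    reports: dict[str, EvaluationReport] = {}
    for arm, mode in (("original features", "original"), ("transfer features", "transfer")):
        Xtr, Xte = build_features(train, test, mode, config)
        fitted = fit_spec(spec, Xtr, train.y)
        reports[arm] = evaluate_classifier(fitted, Xte, test.y)
    rows = []
    for arm, rep in reports.items():
        row = {"feature set": arm, "accuracy": rep.accuracy}
        for code in rep.class_codes:
            row[label_from_code(code).name] = rep.per_class[code]["f1"]
        row["average f1"] = rep.macro_f1
        rows.append(row)
    return pd.DataFrame(rows), reports
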