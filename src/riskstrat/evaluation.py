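"""Performance, coherence and stability diagnostics.

Metrics quantify how well a classifier reproduces the induced quantile class
structure, not predictive generalization to external outcomes: accuracy,
macro-averaged precision/recall/F1, macro one-vs-rest ROC-AUC on predicted
probabilities, and a row-normalized confusion matrix.  Representation
coherence is measured by Pearson/Spearman correlation between the continuous
hybrid representation R(x) and the underlying risk index.  Fold-to-fold
stability is summarized by the mean and sample standard deviation of each
metric across cross-validation folds, together with the log distance to the
optimum log10(1 - m), which spreads out metrics saturating near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

LOG_DISTANCE_FLOOR = 1e-6


@dataclass
class MetricReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    roc_auc_macro: float | None
    confusion_normalized: pd.DataFrame
    n_evaluated: int
    flags: dict = field(default_factory=dict)

    def scalars(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "roc_auc_macro": self.roc_auc_macro,
        }


def _macro_ovr_auc(
    y_true: np.ndarray, probabilities: np.ndarray, classes: np.ndarray
) -> tuple[float | None, list]:
    """Macro one-vs-rest ROC-AUC, tolerating classes absent from the truth."""
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < 2:
        return None, ["roc_auc_undefined_single_class"]
    flags = []
    if len(present) < len(classes):
        warnings.warn(
            "classes absent from the truth are excluded from macro ROC-AUC",
            stacklevel=3,
        )
        flags.append("roc_auc_excluded_absent_classes")
    aucs = []
    for c in present:
        col = int(np.flatnonzero(classes == c)[0])
        aucs.append(roc_auc_score((y_true == c).astype(int), probabilities[:, col]))
    return float(np.mean(aucs)), flags


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probabilities: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> MetricReport:
    """Accuracy, macro precision/recall/F1, macro OvR ROC-AUC and confusion.

    Macro averages are unweighted over the classes present in the truth;
    a class that receives no predictions contributes precision 0 (with a
    warning from scikit-learn suppressed into a flag).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    present = np.array([c for c in classes if np.any(y_true == c)])

    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    flags: dict = {}
    if len(present) < len(classes):
        flags["classes_absent_from_truth"] = [
            c.item() if hasattr(c, "item") else c
            for c in classes
            if not np.any(y_true == c)
        ]
        warnings.warn(
            "classes absent from the truth are excluded from macro averages",
            stacklevel=2,
        )

    auc = None
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(y_true), len(classes)):
            raise ValueError("probability matrix shape mismatch")
        auc, auc_flags = _macro_ovr_auc(y_true, probabilities, classes)
        for f in auc_flags:
            flags[f] = True

    raw = confusion_matrix(y_true, y_pred, labels=classes)
    row_sums = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, raw / np.where(row_sums == 0, 1, row_sums), np.nan)
    confusion = pd.DataFrame(norm, index=classes, columns=classes)

    return MetricReport(
        accuracy=float(acc),
        precision_macro=float(prec),
        recall_macro=float(rec),
        f1_macro=float(f1),
        roc_auc_macro=auc,
        confusion_normalized=confusion,
        n_evaluated=len(y_true),
        flags=flags,
    )


def representation_correlation(
    R_values: np.ndarray, risk_index: np.ndarray
) -> dict[str, float]:
    """Pearson and Spearman correlation between R(x) and the risk index."""
    R_values = np.asarray(R_values, dtype=float)
    risk_index = np.asarray(risk_index, dtype=float)
    if len(R_values) != len(risk_index):
        raise ValueError("vectors have different lengths")
    if len(R_values) < 3:
        raise ValueError("need at least 3 records for correlation")
    if np.ptp(R_values) == 0:
        raise ValueError("R_values is constant; correlation undefined")
    if np.ptp(risk_index) == 0:
        raise ValueError("risk_index is constant; correlation undefined")
    pearson = stats.pearsonr(R_values, risk_index).statistic
    spearman = stats.spearmanr(R_values, risk_index).statistic
    return {"pearson": float(pearson), "spearman": float(spearman)}


@dataclass
class StabilityReport:
    fold_values: dict[str, np.ndarray]
    mean: dict[str, float]
    std: dict[str, float]  # sample std, ddof=1
    log_distance: dict[str, np.ndarray]
    capped: dict[str, np.ndarray]
    floor: float = LOG_DISTANCE_FLOOR

    def frame(self) -> pd.DataFrame:
        rows = []
        for metric, vals in self.fold_values.items():
            for fold, (v, d, c) in enumerate(
                zip(vals, self.log_distance[metric], self.capped[metric])
            ):
                rows.append(
                    {
                        "metric": metric,
                        "fold": fold,
                        "value": v,
                        "log_distance": d,
                        "capped": bool(c),
                    }
                )
        return pd.DataFrame(rows)


def cv_stability(
    fold_metrics: Mapping[str, Sequence[float]],
    floor: float = LOG_DISTANCE_FLOOR,
) -> StabilityReport:
    """Fold dispersion summary: mean, sample std and log10(1 - m) per fold.

    Folds where a metric saturates (1 - m below ``floor``) get the capped
    sentinel log10(floor) and are flagged.
    """
    values = {k: np.asarray(v, dtype=float) for k, v in fold_metrics.items()}
    for k, v in values.items():
        if len(v) < 2:
            raise ValueError(f"metric {k!r} needs at least 2 fold values")
    mean = {k: float(v.mean()) for k, v in values.items()}
    std = {k: float(v.std(ddof=1)) for k, v in values.items()}
    log_distance = {}
    capped = {}
    for k, v in values.items():
        gap = 1.0 - v
        cap_mask = gap < floor
        log_distance[k] = np.where(cap_mask, np.log10(floor), np.log10(np.maximum(gap, floor)))
        capped[k] = cap_mask
    return StabilityReport(
        fold_values=values,
        mean=mean,
        std=std,
        log_distance=log_distance,
        capped=capped,
        floor=floor,
    )


def fold_metric_values(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    fold_assignments: np.ndarray,
    fit_fn: Callable[[np.ndarray, np.ndarray], object],
) -> dict[str, list[float]]:
    """Per-fold validation metrics for a model family.

    ``fit_fn(X_train, y_train)`` must return an object with ``predict`` and
    ``predict_proba``.  Fold metrics are computed on each fold's validation
    part within the training partition (the evaluation partition is never
    involved).
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    out: dict[str, list[float]] = {
        "accuracy": [],
        "f1_macro": [],
        "roc_auc_macro": [],
    }
    for fid in np.unique(fold_assignments):
        val = fold_assignments == fid
        model = fit_fn(Xa[~val], y[~val])
        pred = model.predict(Xa[val])
        proba = model.predict_proba(Xa[val])
        report = classification_metrics(y[val], pred, proba, classes=classes)
        out["accuracy"].append(report.accuracy)
        out["f1_macro"].append(report.f1_macro)
        if report.roc_auc_macro is not None:
            out["roc_auc_macro"].append(report.roc_auc_macro)
    return out
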