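"""Convex hybrid of a linear and a nonlinear classifier.

The hybrid risk model combines a multinomial logistic regression (global,
linear, stable) and a random forest (nonlinear, interaction-aware) through a
convex combination of their class-probability outputs,

    R(x) = w * f_lin(x) + (1 - w) * f_rf(x),   0 <= w <= 1,

where the scalar mixing weight is chosen on a discrete grid by 5-fold
cross-validation on the training partition, minimizing multiclass
cross-entropy of the combined probabilities (macro-F1 is recorded alongside).
Both base models are then retrained on the full training partition with the
winning weight.  The continuous risk representation used by correlation and
attribution diagnostics is the expected ordinal class under the combined
probabilities.

Everything here operates strictly on the training partition defined by a
:class:`SplitPlan`; the evaluation partition is never touched before final
scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, log_loss
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)

DEFAULT_WEIGHT_GRID = tuple(round(0.1 * k, 1) for k in range(11))


@dataclass
class HybridConfig:
    """Hyperparameters of the hybrid scheme (defaults are the study settings)."""

    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    max_iter: int = 3000
    n_estimators: int = 500
    min_samples_leaf: int = 3
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID
    cv_folds: int = 5
    split_ratio: float = 0.7


@dataclass
class SplitPlan:
    """Stratified 70/30 split plus a stratified 5-fold plan on the train part."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fold_assignments: np.ndarray  # fold id per training record
    labels: np.ndarray
    seed: int
    ratio: float = 0.7


def make_split(
    labels: np.ndarray,
    ratio: float = 0.7,
    seed: int = 0,
    folds: int = 5,
) -> SplitPlan:
    """Stratified train/test split with a stratified fold plan on the train part."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    classes, counts = np.unique(labels, return_counts=True)
    for c, cnt in zip(classes, counts):
        if int(np.floor(cnt * ratio)) < folds:
            raise ValueError(
                f"class {c!r} has too few records ({cnt}) to stratify "
                f"{folds}-fold cross-validation on a {ratio:.0%} training split"
            )
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=labels, random_state=seed
    )
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignments = np.empty(len(train_idx), dtype=int)
    for fold_id, (_, val_pos) in enumerate(
        skf.split(np.zeros(len(train_idx)), labels[train_idx])
    ):
        fold_assignments[val_pos] = fold_id
    return SplitPlan(
        train_indices=train_idx,
        test_indices=test_idx,
        fold_assignments=fold_assignments,
        labels=labels,
        seed=seed,
        ratio=ratio,
    )


def _fit_linear(
    X: np.ndarray, y: np.ndarray, config: HybridConfig, seed: int, C: float | None = None
) -> LogisticRegression:
    if C is None and len(config.C_grid) > 1:
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            LogisticRegression(max_iter=config.max_iter),
            {"C": list(config.C_grid)},
            scoring="f1_macro",
            cv=cv,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            search.fit(X, y)
        return search.best_estimator_
    model = LogisticRegression(
        max_iter=config.max_iter, C=C if C is not None else config.C_grid[0]
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                f"linear solver did not converge within {model.max_iter} iterations "
                f"(n_iter={getattr(model, 'n_iter_', '?')})",
                stacklevel=2,
            )
    return model


def fit_base_models(
    X: np.ndarray,
    y: np.ndarray,
    config: HybridConfig | None = None,
    seed: int = 0,
    C: float | None = None,
) -> tuple[LogisticRegression, RandomForestClassifier]:
    """Fit the logistic regression and the random forest on the same data.

    The logistic regularization strength is chosen from ``config.C_grid`` by
    cross-validated macro-F1 unless ``C`` is pinned.  The forest is seeded.
    """
    config = config or HybridConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    linear = _fit_linear(X, y, config, seed, C)
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        min_samples_leaf=config.min_samples_leaf,
        random_state=seed,
    )
    forest.fit(X, y)
    return linear, forest


def combine(
    prob_linear: np.ndarray,
    prob_nonlinear: np.ndarray,
    w: float,
    classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convex combination of two probability matrices.

    Returns the combined probabilities, the predicted class per row (argmax,
    ties to the lower class), and the continuous representation R(x) = the
    expected ordinal class under the combined distribution.
    """
    P1 = np.asarray(prob_linear, dtype=float)
    P2 = np.asarray(prob_nonlinear, dtype=float)
    if P1.shape != P2.shape:
        raise ValueError(f"probability shapes differ: {P1.shape} vs {P2.shape}")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    combined = w * P1 + (1.0 - w) * P2
    class_values = (
        np.asarray(classes) if classes is not None else np.arange(P1.shape[1])
    )
    pred = class_values[np.argmax(combined, axis=1)]
    R = combined @ class_values.astype(float)
    return combined, pred, R


@dataclass
class WeightSearchResult:
    best_w: float
    grid: tuple[float, ...]
    mean_loss: np.ndarray  # per grid candidate
    mean_f1: np.ndarray
    folds_used: int


def search_weights(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] | None = None,
    folds: int = 5,
    seed: int = 0,
    config: HybridConfig | None = None,
    C: float | None = None,
    fold_assignments: np.ndarray | None = None,
) -> WeightSearchResult:
    """Grid search of the convex mixing weight by K-fold cross-validation.

    For each fold, both base models are fitted on the fold-train part once
    and their validation probabilities are mixed for every candidate weight
    (mathematically identical to refitting per candidate).  The winner
    minimizes mean multiclass cross-entropy; ties go to the candidate with
    the larger nonlinear share (smaller ``w``).
    """
    config = config or HybridConfig()
    grid = tuple(grid) if grid is not None else config.weight_grid
    if not grid or any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError("weight grid must be a non-empty subset of [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    all_classes = np.unique(y)

    if fold_assignments is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_assignments = np.empty(len(y), dtype=int)
        for fid, (_, val) in enumerate(skf.split(X, y)):
            fold_assignments[val] = fid
    fold_ids = np.unique(fold_assignments)

    losses = []
    f1s = []
    for fid in fold_ids:
        val_mask = fold_assignments == fid
        y_tr, y_val = y[~val_mask], y[val_mask]
        if len(np.unique(y_tr)) < len(all_classes):
            warnings.warn(f"fold {fid} lacks a class in its training part; skipped")
            continue
        linear, forest = fit_base_models(
            X[~val_mask], y_tr, config, seed=seed + int(fid), C=C
        )
        P1 = linear.predict_proba(X[val_mask])
        P2 = forest.predict_proba(X[val_mask])
        fold_loss = np.empty(len(grid))
        fold_f1 = np.empty(len(grid))
        for i, w in enumerate(grid):
            combined, pred, _ = combine(P1, P2, w, classes=linear.classes_)
            fold_loss[i] = log_loss(y_val, combined, labels=all_classes)
            fold_f1[i] = f1_score(y_val, pred, average="macro", zero_division=0)
        losses.append(fold_loss)
        f1s.append(fold_f1)
    if not losses:
        raise ValueError("every cross-validation fold was skipped")

    mean_loss = np.mean(losses, axis=0)
    mean_f1 = np.mean(f1s, axis=0)
    # argmin with ties resolved toward the larger nonlinear share (smaller w)
    order = np.lexsort((np.asarray(grid), mean_loss))
    best_w = float(grid[order[0]])
    return WeightSearchResult(
        best_w=best_w,
        grid=grid,
        mean_loss=mean_loss,
        mean_f1=mean_f1,
        folds_used=len(losses),
    )


class HybridModel:
    """Fitted convex hybrid of a logistic regression and a random forest.

    Parameters
    ----------
    config:
        Hyperparameters; defaults follow the study configuration (500 trees,
        leaf size 3, max_iter 3000, weight grid 0.0–1.0 in steps of 0.1,
        5-fold weight search).
    seed:
        Single seed fanned out to the C selection, the fold plan and the
        forest.
    """

    def __init__(self, config: HybridConfig | None = None, seed: int = 0) -> None:
        self.config = config or HybridConfig()
        self.seed = seed
        self.linear_: LogisticRegression | None = None
        self.forest_: RandomForestClassifier | None = None
        self.w_: float | None = None
        self.feature_names_: list[str] | None = None
        self.classes_: np.ndarray | None = None
        self.training_metadata: dict = {}

    # ------------------------------------------------------------------
    def fit(
        self,
        X: pd.DataFrame | np.ndarray,
        y: np.ndarray,
        fold_assignments: np.ndarray | None = None,
    ) -> "HybridModel":
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            self.feature_names_ = None
            Xa = np.asarray(X, dtype=float)
        y = np.asarray(y)

        # pin the linear regularization once on the full training partition
        probe = _fit_linear(Xa, y, self.config, self.seed)
        C_star = float(probe.C)

        result = search_weights(
            Xa,
            y,
            grid=self.config.weight_grid,
            folds=self.config.cv_folds,
            seed=self.seed,
            config=self.config,
            C=C_star,
            fold_assignments=fold_assignments,
        )
        self.w_ = result.best_w
        self.linear_, self.forest_ = fit_base_models(
            Xa, y, self.config, seed=self.seed, C=C_star
        )
        self.classes_ = self.linear_.classes_
        self.training_metadata = {
            "seed": self.seed,
            "C": C_star,
            "weight_grid": list(result.grid),
            "cv_mean_loss": result.mean_loss.tolist(),
            "cv_mean_f1_macro": result.mean_f1.tolist(),
            "folds_used": result.folds_used,
            "w_linear": self.w_,
            "w_nonlinear": 1.0 - self.w_,
            "hyperparameters": {
                "max_iter": self.config.max_iter,
                "n_estimators": self.config.n_estimators,
                "min_samples_leaf": self.config.min_samples_leaf,
            },
        }
        return self

    # ------------------------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        """Convex weight vector (linear share, nonlinear share)."""
        self._check_fitted()
        return np.array([self.w_, 1.0 - self.w_])

    def _check_fitted(self) -> None:
        if self.linear_ is None or self.forest_ is None or self.w_ is None:
            raise ValueError("HybridModel is not fitted")

    def _align(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names_ is not None:
                missing = [c for c in self.feature_names_ if c not in X.columns]
                if missing:
                    raise ValueError(f"records lack signal(s): {missing}")
                X = X[self.feature_names_]
            return X.to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        Xa = self._align(X)
        combined, _, _ = combine(
            self.linear_.predict_proba(Xa),
            self.forest_.predict_proba(Xa),
            self.w_,
            classes=self.classes_,
        )
        return combined

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        Xa = self._align(X)
        _, pred, _ = combine(
            self.linear_.predict_proba(Xa),
            self.forest_.predict_proba(Xa),
            self.w_,
            classes=self.classes_,
        )
        return pred

    def representation(self, X) -> np.ndarray:
        """Continuous representation R(x): expected ordinal class."""
        self._check_fitted()
        Xa = self._align(X)
        _, _, R = combine(
            self.linear_.predict_proba(Xa),
            self.forest_.predict_proba(Xa),
            self.w_,
            classes=self.classes_,
        )
        return R

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        self._check_fitted()
        joblib.dump(
            {
                "config": self.config,
                "seed": self.seed,
                "linear": self.linear_,
                "forest": self.forest_,
                "w": self.w_,
                "feature_names": self.feature_names_,
                "classes": self.classes_,
                "training_metadata": self.training_metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "HybridModel":
        payload = joblib.load(path)
        model = cls(config=payload["config"], seed=payload["seed"])
        model.linear_ = payload["linear"]
        model.forest_ = payload["forest"]
        model.w_ = payload["w"]
        model.feature_names_ = payload["feature_names"]
        model.classes_ = payload["classes"]
        model.training_metadata = payload["training_metadata"]
        return model
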