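"""Binary olive-fly classification: dataset split, RF + SVM, AND-ensemble.

The classification task is binary — olive fly versus everything else —
on raw 32x32x3 crops flattened to 3072 intensity-scaled features.  Two
classical learners are trained on the same features:

* a random forest (bootstrap-resampled decision trees, majority vote),
  final hyperparameters 3 estimators, max depth 20, min samples split 5;
* a support-vector machine solving the kernelized dual problem
  ``max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)`` subject
  to ``0 <= a_i <= C`` and ``sum_i a_i y_i = 0``, final hyperparameters
  polynomial kernel, C = 0.1, gamma = 1.

The deployed verdict is the logical AND of the two models on the
positive class: an element is called an olive fly only when both agree.
This trades false negatives up for false positives down, which is the
desired behaviour for a pest alarm that must not cry wolf.

The RF-versus-cautious-SVM asymmetry and the ensemble rule are the point
of this module; the underlying tree and SVM solvers are scikit-learn's.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import (
    CROP_SIZE,
    ElementCrop,
    FlytrapError,
    LabelledDataset,
    POSITIVE_LABEL,
    SingleClassError,
    to_binary_label,
)

_N_FEATURES = CROP_SIZE * CROP_SIZE * 3
_BUNDLE_SCHEMA = "flytrap-bundle-1"


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (defaults are the deployed values)."""

    n_estimators: int = 3
    max_depth: int = 20
    min_samples_split: int = 5
    criterion: str = "gini"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    """SVM hyperparameters (defaults are the deployed values).

    ``C`` penalizes training errors and bounds every dual coefficient;
    ``gamma`` scales the kernel; the polynomial degree applies only to
    the polynomial kernel.
    """

    kernel: str = "poly"
    C: float = 0.1
    gamma: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


def split_counts(counts: dict[str, int] | list[int],
                 val_fraction: float = 0.1) -> list[tuple[int, int]]:
    """Per-class (train, validation) sizes for a 9:1-style split.

    Validation size is ``floor(count * val_fraction)``; the remainder
    trains.  A class with zero samples contributes (0, 0).
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    values = list(counts.values()) if isinstance(counts, dict) else list(counts)
    out = []
    for n in values:
        if n < 0:
            raise ValueError("class counts must be non-negative")
        n_val = int(np.floor(n * val_fraction))
        out.append((n - n_val, n_val))
    return out


def split_dataset(dataset: LabelledDataset, val_fraction: float = 0.1,
                  seed: int = 0) -> tuple[LabelledDataset, LabelledDataset]:
    """Seeded stratified split into training and validation partitions.

    Membership is chosen by a per-class seeded shuffle; per-class sizes
    follow :func:`split_counts`.  Augmentation, if any, must be applied
    afterwards and only to the returned training partition.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.labels3)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for lab in sorted(set(dataset.labels3)):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        (_, n_val), = split_counts([idx.size], val_fraction)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return (dataset.subset(sorted(train_idx), partition="train"),
            dataset.subset(sorted(val_idx), partition="validation"))


def featurize(crop: ElementCrop | np.ndarray) -> np.ndarray:
    """Flatten a 32x32x3 patch to a unit-scaled feature vector of length 3072."""
    patch = crop.patch if isinstance(crop, ElementCrop) else np.asarray(crop)
    if patch.shape != (CROP_SIZE, CROP_SIZE, 3):
        raise ValueError(
            f"expected a {CROP_SIZE}x{CROP_SIZE}x3 patch, got shape {patch.shape}")
    return patch.astype(np.float64).ravel() / 255.0


def featurize_all(crops: list[ElementCrop | np.ndarray]) -> np.ndarray:
    """Feature matrix, one row per crop."""
    if not crops:
        return np.empty((0, _N_FEATURES))
    return np.stack([featurize(c) for c in crops])


def _check_two_classes(y: np.ndarray) -> None:
    present = set(np.unique(y).tolist())
    if len(present) < 2:
        missing = sorted({POSITIVE_LABEL, "others"} - present)
        raise SingleClassError(
            f"training labels contain a single class {sorted(present)}; "
            f"missing {missing}")


def train_rf(train: LabelledDataset, config: RFConfig = RFConfig()
             ) -> RandomForestClassifier:
    """Fit the random forest on binary labels; seeded and reproducible."""
    X = featurize_all(train.crops)
    y = np.asarray(train.labels2)
    _check_two_classes(y)
    rf = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        criterion=config.criterion,
        bootstrap=config.bootstrap,
        random_state=config.seed,
    )
    rf.fit(X, y)
    return rf


def train_svm(train: LabelledDataset, config: SVMConfig = SVMConfig()) -> SVC:
    """Fit the SVM on binary labels and verify the dual-feasibility box.

    After fitting, every dual coefficient must satisfy ``0 <= a_i <= C``
    and the equality constraint ``sum_i a_i y_i = 0`` must hold within
    tolerance; a violation indicates a failed solve and raises.
    """
    X = featurize_all(train.crops)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    y = np.asarray(train.labels2)
    _check_two_classes(y)
    svm = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma,
              degree=config.degree)
    svm.fit(X, y)
    alphas, alpha_y_sum = svm_dual_coefficients(svm)
    if alphas.min() < -1e-9 or alphas.max() > config.C + 1e-9:
        raise FlytrapError(
            f"SVM dual coefficients violate 0 <= a_i <= C={config.C}")
    if abs(alpha_y_sum) > 1e-6:
        raise FlytrapError(
            f"SVM equality constraint violated: sum a_i y_i = {alpha_y_sum:.3e}")
    return svm


def svm_dual_coefficients(svm: SVC) -> tuple[np.ndarray, float]:
    """(alpha_i for support vectors, sum_i alpha_i y_i) of a fitted SVM.

    scikit-learn stores ``y_i * alpha_i`` per support vector, so the
    alphas are the absolute values and the signed sum is the equality
    constraint residual.
    """
    signed = svm.dual_coef_.ravel()
    return np.abs(signed), float(signed.sum())


@dataclass
class ClassifierBundle:
    """Trained RF + SVM with the AND-ensemble verdict rule.

    ``feature_pipeline`` documents the transform from patch to feature
    vector; both models consume identical features.
    """

    rf: RandomForestClassifier
    svm: SVC
    rf_config: RFConfig = field(default_factory=RFConfig)
    svm_config: SVMConfig = field(default_factory=SVMConfig)
    feature_pipeline: str = "flatten/255"
    positive_label: str = POSITIVE_LABEL

    def predict(self, crops: list[ElementCrop | np.ndarray]) -> pd.DataFrame:
        """Per-crop votes and AND verdict.

        Returns a frame with columns ``rf_vote``, ``svm_vote``,
        ``ensemble`` (label strings) plus ``rf_score`` (fraction of
        trees voting positive) and ``svm_score`` (signed decision value,
        oriented so larger means more positive).
        """
        return ensemble_predict(self, crops)

    def save(self, path: str | Path) -> None:
        """Persist losslessly to a single versioned joblib archive."""
        joblib.dump({
            "schema": _BUNDLE_SCHEMA,
            "rf": self.rf,
            "svm": self.svm,
            "rf_config": self.rf_config,
            "svm_config": self.svm_config,
            "feature_pipeline": self.feature_pipeline,
            "positive_label": self.positive_label,
        }, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierBundle":
        payload = joblib.load(path)
        if payload.get("schema") != _BUNDLE_SCHEMA:
            raise FlytrapError(
                f"{path}: not a classifier bundle (schema "
                f"{payload.get('schema')!r}, expected {_BUNDLE_SCHEMA!r})")
        return cls(rf=payload["rf"], svm=payload["svm"],
                   rf_config=payload["rf_config"],
                   svm_config=payload["svm_config"],
                   feature_pipeline=payload["feature_pipeline"],
                   positive_label=payload["positive_label"])


def train_bundle(train: LabelledDataset, rf_config: RFConfig = RFConfig(),
                 svm_config: SVMConfig = SVMConfig()) -> ClassifierBundle:
    """Train both models on the same training partition."""
    return ClassifierBundle(
        rf=train_rf(train, rf_config),
        svm=train_svm(train, svm_config),
        rf_config=rf_config,
        svm_config=svm_config,
    )


def ensemble_predict(bundle: ClassifierBundle,
                     crops: list[ElementCrop | np.ndarray]) -> pd.DataFrame:
    """AND-ensemble verdicts with both individual votes retained.

    The verdict is the positive label iff the RF vote and the SVM vote
    are both positive; consequently ensemble positives are always a
    subset of each model's positives.
    """
    pos = bundle.positive_label
    if not crops:
        return pd.DataFrame(columns=["rf_vote", "svm_vote", "ensemble",
                                     "rf_score", "svm_score"])
    X = featurize_all(crops)
    rf_vote = bundle.rf.predict(X)
    svm_vote = bundle.svm.predict(X)
    pos_col = list(bundle.rf.classes_).index(pos)
    # fraction of trees voting positive (individual trees predict encoded
    # class indices into classes_)
    tree_votes = np.stack([est.predict(X) for est in bundle.rf.estimators_])
    rf_score = (tree_votes == pos_col).mean(axis=0)
    decision = bundle.svm.decision_function(X)
    # SVC orients the decision toward classes_[1]; flip if needed so that
    # larger always means "more olive fly"
    if list(bundle.svm.classes_)[1] != pos:
        decision = -decision
    verdict = np.where((rf_vote == pos) & (svm_vote == pos), pos, "others")
    return pd.DataFrame({
        "rf_vote": rf_vote,
        "svm_vote": svm_vote,
        "ensemble": verdict,
        "rf_score": rf_score,
        "svm_score": decision,
    })


# ---------------------------------------------------------------------------
# hyperparameter selection

#: Default search grids bracketing the deployed hyperparameters.
DEFAULT_RF_GRID = {
    "n_estimators": [3, 10, 50],
    "max_depth": [5, 10, 20],
    "min_samples_split": [2, 5, 10],
}
DEFAULT_SVM_GRID = {
    "kernel": ["linear", "poly", "rbf"],
    "C": [0.1, 1.0, 10.0],
    "gamma": [0.01, 0.1, 1.0],
}


def _complexity(family: str, params: dict) -> float:
    # simpler-model tie-break: fewer trees, then smaller C
    if family == "rf":
        return params["n_estimators"]
    return params["C"]


def grid_search_cv(train: LabelledDataset, family: str,
                   grid: dict[str, list] | None = None, k: int = 5,
                   seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search scored by stratified k-fold CV accuracy.

    Ties on mean validation accuracy are broken in favour of the simpler
    model (fewer trees for RF, smaller C for SVM), then by grid order.
    Returns the winning parameter dict and the full CV table with one
    row per (grid point, fold).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if family not in ("rf", "svm"):
        raise ValueError(f"unknown model family {family!r}")
    if grid is None:
        grid = DEFAULT_RF_GRID if family == "rf" else DEFAULT_SVM_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")

    X = featurize_all(train.crops)
    y = np.asarray(train.labels2)
    _check_two_classes(y)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < k:
        raise FlytrapError(
            f"stratified {k}-fold CV impossible: smallest class has "
            f"{counts.min()} samples")
    folds = list(StratifiedKFold(n_splits=k, shuffle=True,
                                 random_state=seed).split(X, y))

    keys = list(grid)
    rows = []
    results = []
    for order, values in enumerate(itertools.product(*(grid[k_] for k_ in keys))):
        params = dict(zip(keys, values))
        fold_acc = []
        for fold_id, (tr, va) in enumerate(folds):
            if family == "rf":
                model = RandomForestClassifier(
                    criterion="gini", bootstrap=True, random_state=seed,
                    **params)
            else:
                model = SVC(degree=3, **params)
            model.fit(X[tr], y[tr])
            acc = float((model.predict(X[va]) == y[va]).mean())
            fold_acc.append(acc)
            rows.append({"grid_index": order, **params,
                         "fold": fold_id, "accuracy": acc})
        results.append((float(np.mean(fold_acc)), -_complexity(family, params),
                        -order, params))
    best = max(results)[3]
    return best, pd.DataFrame(rows)
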