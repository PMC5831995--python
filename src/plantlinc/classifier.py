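"""RBF-SVM discrimination of lincRNAs from protein-coding transcripts.

The training protocol: balance the two classes by seeded down-sampling,
hold out a stratified 20% test split, z-score features with the training
split's statistics, grid-search (C, gamma) by mean 10-fold cross-validated
accuracy on the training split, refit the winner on the whole training
split, and report hold-out accuracy. The default grids are the classic
libSVM practical-guide ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import build_feature_matrix
from .io import Transcript

__all__ = [
    "DEFAULT_GRID_C",
    "DEFAULT_GRID_GAMMA",
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LABEL_TOO_SHORT",
    "TrainConfig",
    "LincRNAClassifier",
    "ModelSpec",
    "train",
    "predict",
    "evaluate",
]

DEFAULT_GRID_C: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GRID_GAMMA: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))

LABEL_POSITIVE = "lincRNA_like"
LABEL_NEGATIVE = "PCT_like"
#: sentinel for transcripts too short to carry a full feature vector
LABEL_TOO_SHORT = "too_short"
_MIN_PREDICT_LENGTH = 4


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameter grids and protocol settings for model construction."""

    grid_C: tuple[float, ...] = DEFAULT_GRID_C
    grid_gamma: tuple[float, ...] = DEFAULT_GRID_GAMMA
    folds: int = 10
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.grid_C or not self.grid_gamma:
            raise ValueError("grids must be non-empty")


class LincRNAClassifier(ClassifierMixin, BaseEstimator):
    """Grid-searched RBF support-vector classifier with internal scaling.

    Parameters
    ----------
    grid_C, grid_gamma:
        Candidate values; ties in cross-validated accuracy are broken
        toward the smallest C, then the smallest gamma.
    folds:
        Cross-validation folds used for model selection.
    test_fraction:
        Stratified hold-out fraction used for the reported test accuracy.
    random_state:
        Seed controlling class balancing, the split, and fold shuffling.

    Attributes (after fit)
    ----------------------
    C_, gamma_ : selected hyperparameters.
    mean_, scale_ : per-feature scaling statistics from the training split
        (constant features are flagged in ``constant_mask_`` and left
        unscaled).
    cv_accuracy_ : mean 10-fold CV accuracy of the winning grid point.
    test_accuracy_ : accuracy on the held-out split.
    cv_results_ : DataFrame of (C, gamma, cv_accuracy) for the whole grid.
    train_indices_, test_indices_ : row indices of the split, relative to
        the balanced input matrix.
    """

    def __init__(
        self,
        grid_C: Sequence[float] = DEFAULT_GRID_C,
        grid_gamma: Sequence[float] = DEFAULT_GRID_GAMMA,
        folds: int = 10,
        test_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.grid_C = grid_C
        self.grid_gamma = grid_gamma
        self.folds = folds
        self.test_fraction = test_fraction
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(X).any():
            raise ValueError("feature matrix contains NaN")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {list(classes)}")

        rng = np.random.default_rng(self.random_state)
        X, y = _balance_classes(X, y, classes, rng)
        n_per_class = (y == classes[0]).sum()
        if n_per_class < self.folds:
            raise ValueError(
                f"balanced class size {n_per_class} is smaller than "
                f"folds={self.folds}"
            )

        idx = np.arange(len(y))
        idx_train, idx_test = train_test_split(
            idx,
            test_size=self.test_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        X_train, y_train = X[idx_train], y[idx_train]
        X_test, y_test = X[idx_test], y[idx_test]

        # scaling statistics come from the training split only
        self.mean_ = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        self.constant_mask_ = sd == 0
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        Xs_train = (X_train - self.mean_) / self.scale_

        cv = StratifiedKFold(
            n_splits=self.folds, shuffle=True, random_state=self.random_state
        )
        rows = []
        best = None  # (accuracy, -C, -gamma) maximized -> smallest C/gamma wins ties
        for C in self.grid_C:
            for gamma in self.grid_gamma:
                acc = cross_val_score(
                    SVC(kernel="rbf", C=C, gamma=gamma),
                    Xs_train,
                    y_train,
                    cv=cv,
                    scoring="accuracy",
                ).mean()
                rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
                key = (acc, -C, -gamma)
                if best is None or key > best[0]:
                    best = (key, C, gamma, acc)
        _, self.C_, self.gamma_, self.cv_accuracy_ = best

        self.svm_ = SVC(kernel="rbf", C=self.C_, gamma=self.gamma_)
        self.svm_.fit(Xs_train, y_train)
        self.classes_ = self.svm_.classes_
        self.cv_results_ = pd.DataFrame(rows)
        self.train_indices_ = idx_train
        self.test_indices_ = idx_test
        self.n_features_in_ = X.shape[1]
        self.test_accuracy_ = float(
            (self.predict(X_test) == y_test).mean()
        )
        return self

    # -- inference --------------------------------------------------------

    def _scale(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got {X.shape}"
            )
        return (X - self.mean_) / self.scale_

    def predict(self, X):
        return self.svm_.predict(self._scale(X))

    def decision_function(self, X):
        return self.svm_.decision_function(self._scale(X))


def _balance_classes(X, y, classes, rng) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample the larger class to the size of the smaller (seeded)."""
    idx_a = np.flatnonzero(y == classes[0])
    idx_b = np.flatnonzero(y == classes[1])
    n = min(len(idx_a), len(idx_b))
    keep_a = idx_a if len(idx_a) == n else rng.choice(idx_a, size=n, replace=False)
    keep_b = idx_b if len(idx_b) == n else rng.choice(idx_b, size=n, replace=False)
    keep = np.sort(np.concatenate([keep_a, keep_b]))
    return X[keep], y[keep]


@dataclass
class ModelSpec:
    """A trained lincRNA/PCT model plus everything needed to apply it.

    Carries its own ordered pattern list so predict-time feature extraction
    cannot diverge from training; the kernel is always RBF.
    """

    patterns: tuple[str, ...]
    classifier: LincRNAClassifier
    seed: int
    kernel: str = "RBF"

    @property
    def C(self) -> float:
        return self.classifier.C_

    @property
    def gamma(self) -> float:
        return self.classifier.gamma_

    @property
    def cv_accuracy(self) -> float:
        return self.classifier.cv_accuracy_

    @property
    def test_accuracy(self) -> float:
        return self.classifier.test_accuracy_

    @property
    def scaling(self) -> list[tuple[float, float]]:
        clf = self.classifier
        return list(zip(clf.mean_.tolist(), clf.scale_.tolist()))

    def predict_transcripts(self, transcripts: Sequence[Transcript]) -> dict[str, str]:
        """Label each transcript lincRNA_like / PCT_like.

        Transcripts shorter than 4 nt cannot fill a tetramer window and are
        labeled with the ``too_short`` sentinel; they must be excluded from
        downstream positive sets.
        """
        labels: dict[str, str] = {}
        usable = []
        for t in transcripts:
            if t.length < _MIN_PREDICT_LENGTH:
                labels[t.id] = LABEL_TOO_SHORT
            else:
                usable.append(t)
        if usable:
            feats = build_feature_matrix(usable, self.patterns)
            pred = self.classifier.predict(feats.to_numpy())
            for t, p in zip(usable, pred):
                labels[t.id] = LABEL_POSITIVE if p == 1 else LABEL_NEGATIVE
        return labels

    def decision_values(self, transcripts: Sequence[Transcript]) -> dict[str, float]:
        usable = [t for t in transcripts if t.length >= _MIN_PREDICT_LENGTH]
        if not usable:
            return {}
        feats = build_feature_matrix(usable, self.patterns)
        vals = self.classifier.decision_function(feats.to_numpy())
        return {t.id: float(v) for t, v in zip(usable, vals)}


def train(
    pos_features: pd.DataFrame,
    neg_features: pd.DataFrame,
    cfg: TrainConfig = TrainConfig(),
    patterns: Sequence[str] | None = None,
) -> ModelSpec:
    """Build a ModelSpec from labeled feature matrices (rows = transcripts).

    ``patterns`` defaults to the k-mer columns of the feature matrix (every
    column after orf_length/orf_proportion).
    """
    if list(pos_features.columns) != list(neg_features.columns):
        raise ValueError("positive and negative feature matrices must share columns")
    for name, df in (("positive", pos_features), ("negative", neg_features)):
        if df.empty:
            raise ValueError(f"{name} feature matrix is empty")
        if df.isna().any().any():
            mask = df.isna().to_numpy()
            i, j = map(int, np.argwhere(mask)[0])
            raise ValueError(
                f"NaN feature: transcript {df.index[i]!r}, column {df.columns[j]!r}"
            )
    if patterns is None:
        patterns = tuple(c for c in pos_features.columns if set(c) <= set("ACGT"))
    X = np.vstack([pos_features.to_numpy(), neg_features.to_numpy()])
    y = np.concatenate([np.ones(len(pos_features), dtype=int), np.zeros(len(neg_features), dtype=int)])
    clf = LincRNAClassifier(
        grid_C=tuple(cfg.grid_C),
        grid_gamma=tuple(cfg.grid_gamma),
        folds=cfg.folds,
        test_fraction=cfg.test_fraction,
        random_state=cfg.seed,
    ).fit(X, y)
    return ModelSpec(patterns=tuple(patterns), classifier=clf, seed=cfg.seed)


def predict(model: ModelSpec, transcripts: Sequence[Transcript]) -> dict[str, str]:
    """Apply a trained model; returns id -> label map (see ModelSpec)."""
    if transcripts is None:
        raise ValueError("transcripts must be a collection")
    return model.predict_transcripts(list(transcripts))


def evaluate(
    model: ModelSpec | LincRNAClassifier,
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) on labeled feature rows.

    Labels are 1 (positive / lincRNA) and 0 (negative / PCT). With no
    negative (or no positive) examples the corresponding rate is undefined
    and reported as NaN with a warning.
    """
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("cannot evaluate on empty input")
    clf = model.classifier if isinstance(model, ModelSpec) else model
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    pred = clf.predict(X)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = (tp + tn) / len(y)
    if tp + fn == 0:
        warnings.warn("no positive examples; sensitivity undefined")
        sensitivity = float("nan")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative examples; specificity undefined")
        specificity = float("nan")
    else:
        specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity
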