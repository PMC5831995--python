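"""PCA-based selection of class-discriminative k-mer patterns.

From the 336 candidate composition features (16 dimers + 64 trimers + 256
tetramers) the selector keeps the patterns that best separate a positive
(lincRNA/lncRNA) from a negative (protein-coding) training set:

1. frequencies are z-scored over the pooled set (a dimer lives near 1/16,
   a tetramer near 1/256 — without standardisation PCA would never weight
   a tetramer);
2. PCA is run on the standardised pooled matrix;
3. each component's sample scores are correlated with the class label
   (point-biserial); the most correlated component is the single best
   class-separating axis (oriented so the positive class scores positive);
4. each feature is scored from the component loadings; zero-variance
   features score 0;
5. the top ``n_select`` features (default 10) are returned.

Two scoring rules are available. ``scoring="weighted"`` (default) sums the
loadings over all components, each weighted by its label correlation times
the component's standard deviation; this reconstructs exactly the
projection of the between-class mean-difference vector onto each feature,
so features are ranked by how much they separate the classes.
``scoring="component"`` uses the absolute loading on the single most
label-correlated component; it is simpler but conflates discrimination
with within-class covariance — features that merely co-vary with a
discriminative feature inherit its loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .features import kmer_frequency_matrix
from .io import Transcript

__all__ = [
    "candidate_patterns",
    "KmerPatternSelector",
    "SelectionReport",
    "select_patterns",
    "SUGARCANE_PATTERNS",
    "MAIZE_PATTERNS",
    "PRESET_PATTERNS",
]

#: pattern lists of the two published plant case studies, usable as presets
#: so that prediction can bypass selection
SUGARCANE_PATTERNS = ("AA", "AT", "CA", "CC", "CG", "GA", "GC", "GG", "TG", "TT")
MAIZE_PATTERNS = ("AA", "AC", "CA", "CC", "CCC", "CG", "GA", "GC", "GG", "TG")
PRESET_PATTERNS = {"sugarcane": SUGARCANE_PATTERNS, "maize": MAIZE_PATTERNS}

_CORR_EPS = 1e-6


def candidate_patterns() -> list[str]:
    """All 336 candidate patterns: k ascending, lexicographic within each k."""
    return ["".join(p) for k in (2, 3, 4) for p in product("ACGT", repeat=k)]


class KmerPatternSelector(BaseEstimator):
    """Select the most class-discriminative k-mer frequency features.

    Operates on a numeric matrix whose columns are k-mer frequencies (by
    default the full 336-candidate universe in ``candidate_patterns()``
    order) and a binary label vector (1 = positive class).

    Parameters
    ----------
    n_select:
        Number of patterns to keep.
    scoring:
        "weighted" (default): loadings summed over all components, weighted
        by label correlation x component sd — ranks features by their
        between-class mean separation. "component": |loading| on the single
        most label-correlated component.

    Attributes
    ----------
    selected_patterns_ : list of str, descending discrimination score.
    scores_ : dict mapping every candidate pattern to its score.
    pc_index_ : index of the most class-correlated principal component.
    explained_variance_ : explained variance ratio of that component.
    correlation_ : point-biserial correlation of its scores with the label.
    """

    def __init__(self, n_select: int = 10, scoring: str = "weighted"):
        self.n_select = n_select
        self.scoring = scoring

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        names = list(feature_names) if feature_names is not None else candidate_patterns()
        if len(names) != X.shape[1]:
            raise ValueError(
                f"{X.shape[1]} columns but {len(names)} feature names"
            )
        if self.n_select > len(names):
            raise ValueError(
                f"n_select={self.n_select} exceeds the {len(names)} candidates"
            )
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("exactly two classes are required")
        for c in classes:
            if (y == c).sum() < 2:
                raise ValueError(
                    f"class {c!r} has fewer than 2 members; covariance undefined"
                )
        ybin = (y == classes.max()).astype(float)

        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("every candidate feature is constant over the pooled set")
        Z = (X[:, keep] - mean[keep]) / sd[keep]

        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(Z)

        # point-biserial correlation of each component's scores with the label;
        # rank-deficient components carry numerical noise, not structure, and
        # must not be allowed to fake a correlation
        yc = ybin - ybin.mean()
        denom = np.linalg.norm(scores, axis=0) * np.linalg.norm(yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (scores.T @ yc) / denom, 0.0)
        negligible = pca.explained_variance_ <= 1e-10 * pca.explained_variance_[0]
        corr[negligible] = 0.0

        if self.scoring not in ("weighted", "component"):
            raise ValueError("scoring must be 'weighted' or 'component'")
        degenerate = np.max(np.abs(corr)) < _CORR_EPS
        if degenerate:
            warnings.warn(
                "no discriminative component: classes are indistinguishable; "
                "returning top loadings of PC1"
            )
            idx = 0
        else:
            idx = int(np.argmax(np.abs(corr)))

        r = corr[idx]
        if self.scoring == "component" or degenerate:
            loadings = pca.components_[idx].copy()
            # orient the axis so the positive class has positive mean score
            if r < 0:
                loadings = -loadings
            scores_kept = np.abs(loadings)
        else:
            # sum of loadings weighted by label correlation x component sd:
            # reconstructs the between-class mean-difference direction
            sds = np.sqrt(pca.explained_variance_)
            scores_kept = np.abs((corr * sds) @ pca.components_)
        r = abs(r)

        full = np.zeros(len(names))
        full[keep] = scores_kept
        order = np.argsort(-full, kind="stable")

        self.feature_names_ = names
        self.scores_ = {names[j]: float(full[j]) for j in range(len(names))}
        self.selected_patterns_ = [names[j] for j in order[: self.n_select]]
        self.pc_index_ = idx
        self.explained_variance_ = float(pca.explained_variance_ratio_[idx])
        self.correlation_ = float(r)
        return self

    def get_support(self) -> np.ndarray:
        sel = set(self.selected_patterns_)
        return np.array([n in sel for n in self.feature_names_])

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.get_support()]


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of pattern selection over a labeled training set."""

    selected_patterns: tuple[str, ...]
    scores: dict[str, float]
    pc_index: int
    explained_variance: float
    correlation: float


def select_patterns(
    pos: Sequence[Transcript],
    neg: Sequence[Transcript],
    n_select: int = 10,
    seed: int | None = None,
) -> SelectionReport:
    """Pick the ``n_select`` k-mer patterns separating lincRNAs from PCTs.

    ``seed`` is accepted for interface symmetry; the procedure itself is
    deterministic given the input order.
    """
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    X = kmer_frequency_matrix(list(pos) + list(neg))
    y = np.array([1] * len(pos) + [0] * len(neg))
    sel = KmerPatternSelector(n_select=n_select).fit(
        X.to_numpy(), y, feature_names=list(X.columns)
    )
    return SelectionReport(
        selected_patterns=tuple(sel.selected_patterns_),
        scores=sel.scores_,
        pc_index=sel.pc_index_,
        explained_variance=sel.explained_variance_,
        correlation=sel.correlation_,
    )
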