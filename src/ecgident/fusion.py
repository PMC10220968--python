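"""Feature-level fusion (DWT block + deep block) and subject classification.

The 256 wavelet coefficients and the 128 deep features of each beat are
concatenated into one 384-dimensional hybrid vector and classified with a
random forest (100 trees); RBF-kernel SVM and k-NN baselines are provided
for comparison.  The forest also yields a mean-impurity-decrease ranking of
the fused features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InvalidConfigError, InvalidInputError, InvalidStateError

__all__ = [
    "FusedFeatureSet",
    "ClassifierSpec",
    "FeatureRanking",
    "fuse_features",
    "train_classifier",
    "rank_features",
    "DWT_BLOCK",
    "DEEP_BLOCK",
]

DWT_BLOCK = slice(0, 256)
DEEP_BLOCK = slice(256, 384)


@dataclass
class FusedFeatureSet:
    """n x 384 hybrid features: columns 0-255 wavelet, 256-383 deep."""

    matrix: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.matrix.shape[1] != 384:
            raise InvalidInputError(f"fused features must have 384 columns, got {self.matrix.shape[1]}")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise InvalidInputError("labels must align with feature rows")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidInputError("fused features contain missing/non-finite values")


@dataclass
class ClassifierSpec:
    """Which classifier to fit and with what hyperparameters."""

    kind: str = "random_forest"
    n_trees: int = 100
    random_state: int = 42
    knn_k: int = 5
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "svm_rbf", "knn"):
            raise InvalidConfigError(f"unknown classifier kind {self.kind!r}")
        if self.n_trees < 1:
            raise InvalidConfigError("n_trees must be >= 1")


@dataclass
class FeatureRanking:
    """Features sorted by normalized mean impurity decrease (descending)."""

    indices: np.ndarray
    scores: np.ndarray
    blocks: list[str]


def fuse_features(dwt: np.ndarray, deep: np.ndarray, labels=None, provenance=None) -> FusedFeatureSet:
    """Horizontally concatenate aligned DWT (n x 256) and deep (n x 128) blocks."""
    dwt = np.atleast_2d(np.asarray(dwt, dtype=float))
    deep = np.atleast_2d(np.asarray(deep, dtype=float))
    if dwt.shape[0] != deep.shape[0]:
        raise InvalidInputError(
            f"row-count mismatch: {dwt.shape[0]} DWT rows vs {deep.shape[0]} deep rows"
        )
    if dwt.shape[1] != 256 or deep.shape[1] != 128:
        raise InvalidInputError("expected 256 DWT and 128 deep columns")
    if labels is None:
        labels = np.arange(dwt.shape[0])
    return FusedFeatureSet(
        matrix=np.hstack([dwt, deep]), labels=labels, provenance=provenance or {}
    )


def make_classifier(spec: ClassifierSpec):
    if spec.kind == "random_forest":
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=spec.random_state)
    if spec.kind == "svm_rbf":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(C=spec.svm_c, gamma=spec.svm_gamma, kernel="rbf")),
            ]
        )
    return Pipeline(
        [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=spec.knn_k))]
    )


def train_classifier(features, labels, spec: ClassifierSpec | None = None):
    """Fit the requested classifier on (features, labels)."""
    spec = spec or ClassifierSpec()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError("labels must align with feature rows")
    if np.unique(y).size < 2:
        raise InvalidInputError("training requires at least 2 classes")
    clf = make_classifier(spec)
    clf.fit(X, y)
    return clf


def rank_features(forest: RandomForestClassifier, n_top: int | None = None) -> FeatureRanking:
    """Rank fused features by the forest's normalized mean impurity decrease."""
    importances = getattr(forest, "feature_importances_", None)
    if importances is None:
        raise InvalidStateError("rank_features requires a fitted random forest")
    order = np.argsort(importances)[::-1]
    if n_top is not None:
        order = order[:n_top]
    blocks = ["dwt" if i < DWT_BLOCK.stop else "deep" for i in order]
    return FeatureRanking(indices=order, scores=importances[order], blocks=blocks)
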