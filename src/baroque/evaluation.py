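"""Fitness evaluation of candidate feature masks.

A wrapper selector scores a mask by training a classifier on the selected
columns and measuring held-out accuracy, accuracy = (TP+TN)/(TP+FP+TN+FN)
in the binary case and #correct/#total in general.  Ties in accuracy are
broken toward fewer selected features (fewer features mean less
computation on-device).

Metaheuristics revisit masks constantly, so :class:`MaskObjective`
memoizes results by the exact bit pattern; repeated queries are
byte-identical and free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from ._nn import SmallConvNet
from .core import FeatureMatrix

__all__ = [
    "ConfusionCounts",
    "FitnessResult",
    "EvaluatorSpec",
    "accuracy",
    "better",
    "evaluate_mask",
    "MaskObjective",
    "FunctionObjective",
    "ConvNetClassifier",
    "build_convnet_evaluator",
    "confusion_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for one class (one-vs-rest)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0


@dataclass(frozen=True, order=False)
class FitnessResult:
    """Fitness f(s) of a mask: accuracy plus the selected-feature count."""

    accuracy: float
    n_selected: int
    evaluator_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")
        if self.n_selected < 1:
            raise ValueError("a scored mask must select at least one feature")


def accuracy(predictions, labels) -> float:
    """Multi-class accuracy #correct / #total."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float(np.mean(predictions == labels))


def better(a: FitnessResult, b: FitnessResult) -> bool:
    """True iff a strictly beats b: higher accuracy, or equal accuracy
    with fewer selected features. Equal on both -> False (incumbent wins)."""
    if a.evaluator_id != b.evaluator_id:
        raise ValueError(
            f"incomparable fitness results: {a.evaluator_id!r} vs {b.evaluator_id!r}"
        )
    if a.accuracy != b.accuracy:
        return a.accuracy > b.accuracy
    return a.n_selected < b.n_selected


def confusion_summary(y_true, y_pred) -> dict[str, dict[str, int]]:
    """Per-class one-vs-rest TP/FP/TN/FN counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    out = {}
    for i, c in enumerate(classes):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        tn = int(total - tp - fp - fn)
        out[str(c)] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    return out


@dataclass(frozen=True)
class EvaluatorSpec:
    """Which classifier scores a mask, and under which protocol.

    kind: "knn" (k-nearest neighbours, default k=2), "svm" (RBF kernel,
    default gamma=0.001), or "cnn" (the small 1-D convnet).  protocol:
    "holdout" (stratified split, default 70/30) or "kfold".
    """

    kind: str = "knn"
    k: int = 2
    gamma: float = 0.001
    kernel: str = "rbf"
    protocol: str = "holdout"
    train_fraction: float = 0.7
    n_folds: int = 10
    cnn_epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"knn", "svm", "cnn"}:
            raise ValueError(f"unknown evaluator kind {self.kind!r}")
        if self.protocol not in {"holdout", "kfold"}:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.k < 1 or self.n_folds < 2:
            raise ValueError("k >= 1 and n_folds >= 2 required")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def evaluator_id(self) -> str:
        core = {"knn": f"knn(k={self.k})", "svm": f"svm(gamma={self.gamma},{self.kernel})",
                "cnn": f"cnn(epochs={self.cnn_epochs})"}[self.kind]
        proto = (f"holdout({self.train_fraction})" if self.protocol == "holdout"
                 else f"kfold({self.n_folds})")
        return f"{core}/{proto}/seed={self.seed}"

    def with_seed(self, seed: int) -> "EvaluatorSpec":
        return replace(self, seed=seed)


class ConvNetClassifier:
    """sklearn-style wrapper around the 1-D convnet, with label encoding
    and train-set standardization."""

    def __init__(self, n_classes: int | None = None, epochs: int = 30,
                 lr: float = 1e-3, seed: int = 0):
        self.n_classes = n_classes
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.net: SmallConvNet | None = None

    def fit(self, x: np.ndarray, y) -> "ConvNetClassifier":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.classes_, y_enc = np.unique(np.asarray(y), return_inverse=True)
        n_classes = self.n_classes or len(self.classes_)
        self._mu = x.mean(axis=0)
        self._sd = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        self.net = SmallConvNet(x.shape[1], n_classes, lr=self.lr, seed=self.seed)
        self.net.fit((x - self._mu) / self._sd, y_enc, epochs=self.epochs,
                     seed=self.seed)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.net.predict_proba((x - self._mu) / self._sd)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(x).argmax(axis=1)]


def build_convnet_evaluator(n_features: int, n_classes: int, epochs: int = 30,
                            lr: float = 1e-3, seed: int = 0) -> ConvNetClassifier:
    """Construct the convnet classifier for a given input width.

    Needs n_features >= 8 so that both max-pooling stages (kernel 2,
    stride 2, each halving the length with floor) keep a positive length.
    """
    if n_features < 8:
        raise ValueError("convnet evaluator needs at least 8 features")
    return ConvNetClassifier(n_classes=n_classes, epochs=epochs, lr=lr, seed=seed)


def _make_classifier(spec: EvaluatorSpec):
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k)
    if spec.kind == "svm":
        return SVC(gamma=spec.gamma, kernel=spec.kernel, random_state=spec.seed)
    return ConvNetClassifier(epochs=spec.cnn_epochs, seed=spec.seed)


def _score(matrix: FeatureMatrix, mask: np.ndarray, spec: EvaluatorSpec) -> float:
    x = matrix.values(mask)
    y = matrix.labels
    if spec.protocol == "holdout":
        xtr, xte, ytr, yte = train_test_split(
            x, y, train_size=spec.train_fraction, random_state=spec.seed,
            stratify=y)
        clf = _make_classifier(spec).fit(xtr, ytr)
        return accuracy(clf.predict(xte), yte)
    folds = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                            random_state=spec.seed)
    accs = []
    for tr, te in folds.split(x, y):
        clf = _make_classifier(spec).fit(x[tr], y[tr])
        accs.append(accuracy(clf.predict(x[te]), y[te]))
    return float(np.mean(accs))


def evaluate_mask(mask: np.ndarray, matrix: FeatureMatrix,
                  spec: EvaluatorSpec) -> FitnessResult:
    """Score one mask (un-memoized; see MaskObjective for cached use)."""
    mask = np.asarray(mask).astype(np.uint8)
    if mask.shape[0] != matrix.n_features:
        raise ValueError(
            f"mask length {mask.shape[0]} != feature count {matrix.n_features}")
    n_selected = int(mask.sum())
    if n_selected == 0:
        raise ValueError("cannot evaluate an all-zero mask (no features selected)")
    acc = _score(matrix, mask, spec)
    return FitnessResult(accuracy=acc, n_selected=n_selected,
                         evaluator_id=spec.evaluator_id, seed=spec.seed)


class MaskObjective:
    """Memoizing mask -> FitnessResult objective bound to a feature table.

    n_evaluations counts classifier trainings (cache misses); n_queries
    counts all calls.  Disabling the cache never changes returned values,
    only the cost.
    """

    def __init__(self, matrix: FeatureMatrix, spec: EvaluatorSpec,
                 cache: bool = True):
        self.matrix = matrix
        self.spec = spec
        self.n_features = matrix.n_features
        self.cache_enabled = cache
        self._cache: dict[bytes, FitnessResult] = {}
        self.n_evaluations = 0
        self.n_queries = 0

    @property
    def evaluator_id(self) -> str:
        return self.spec.evaluator_id

    def __call__(self, mask: np.ndarray) -> FitnessResult:
        mask = np.asarray(mask).astype(np.uint8)
        self.n_queries += 1
        key = mask.tobytes()
        if self.cache_enabled and key in self._cache:
            return self._cache[key]
        result = evaluate_mask(mask, self.matrix, self.spec)
        self.n_evaluations += 1
        if self.cache_enabled:
            self._cache[key] = result
        return result


class FunctionObjective:
    """Objective over an arbitrary accuracy function of the mask.

    Used for deterministic toy landscapes (e.g. fraction of bits matching
    a hidden target) where the global optimum is known by enumeration.
    """

    def __init__(self, fn: Callable[[np.ndarray], float], n_features: int,
                 evaluator_id: str = "toy"):
        self.fn = fn
        self.n_features = n_features
        self.evaluator_id = evaluator_id
        self._cache: dict[bytes, FitnessResult] = {}
        self.n_evaluations = 0
        self.n_queries = 0

    def __call__(self, mask: np.ndarray) -> FitnessResult:
        mask = np.asarray(mask).astype(np.uint8)
        self.n_queries += 1
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        if mask.sum() == 0:
            raise ValueError("cannot evaluate an all-zero mask")
        result = FitnessResult(accuracy=float(self.fn(mask)),
                               n_selected=int(mask.sum()),
                               evaluator_id=self.evaluator_id)
        self.n_evaluations += 1
        self._cache[key] = result
        return result
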