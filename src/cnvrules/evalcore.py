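"""Evaluation machinery: stratified CV, SMOTE, multiclass MCC, classifiers.

Cross-validation pools out-of-fold predictions into a single confusion
matrix (rows = true class, columns = predicted, in declared class order)
and scores it with Gorodkin's multiclass generalization of the Matthews
correlation coefficient (the Rk statistic). Class rebalancing follows the
SMOTE recipe: synthetic minority samples interpolated on segments between
a minority point and one of its k nearest same-class neighbors, until all
classes match the majority size.

SMOTE placement relative to CV is controlled by ``smote_policy``:

* ``none`` — no rebalancing;
* ``train_folds_only`` — rebalance each training fold after splitting
  (no information leaks into the held-out fold; the default);
* ``before_split`` — rebalance the whole dataset first, then split.
  Synthetic points then share generators with test points, which inflates
  scores; provided to emulate protocols that oversample up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import LinearSVC

from .dataio import LabeledDataset

__all__ = [
    "SMOTE_POLICIES",
    "SubsetEvaluation",
    "stratified_kfold",
    "smote_oversample",
    "multiclass_mcc",
    "per_class_accuracy",
    "OvrMaxMarginClassifier",
    "train_ovr_classifier",
    "cross_validate",
]

SMOTE_POLICIES = ("none", "train_folds_only", "before_split")


@dataclass
class SubsetEvaluation:
    """Cross-validated performance of one feature subset."""

    subset_size: int
    mcc: float
    class_accuracy: np.ndarray  # per class, NaN when a class has no true samples
    confusion: np.ndarray  # pooled out-of-fold counts, true x predicted
    classifier: str
    smote_policy: str
    seed: int
    n_folds: int

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


def stratified_kfold(labels: Sequence, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1) per sample.

    Fold sizes differ by at most one overall and within every class. A
    class smaller than k is allowed but triggers a warning, since some
    folds will then lack it.
    """
    y = np.asarray(labels)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if small.size:
        warnings.warn(
            f"class(es) smaller than k={k}: {', '.join(map(str, small))}; "
            "some folds will lack them",
            RuntimeWarning,
            stacklevel=2,
        )
    # shuffled round-robin per class, with the start offset carried across
    # classes so overall fold sizes also stay within one of each other
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in classes:
        idx = rng.permutation(np.nonzero(y == cls)[0])
        folds[idx] = (offset + np.arange(len(idx))) % k
        offset = (offset + len(idx)) % k
    return folds


def smote_oversample(
    features: np.ndarray,
    labels: Sequence,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority size.

    Each synthetic point is x + u * (nn - x) with u ~ Uniform(0, 1),
    between a minority sample x and one of its k nearest same-class
    neighbors (Euclidean). Originals are passed through unchanged, with
    synthetic rows appended.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    new_X = [X]
    new_y = [y]
    for cls, count in zip(classes, counts):
        n_new = int(majority - count)
        if n_new == 0:
            continue
        pts = X[y == cls]
        if count == 1:
            warnings.warn(
                f"class {cls!r} has a single member; duplicating it", RuntimeWarning,
                stacklevel=2,
            )
            synth = np.repeat(pts, n_new, axis=0)
        else:
            k = k_neighbors
            if count <= k_neighbors:
                k = count - 1
                warnings.warn(
                    f"class {cls!r} has {count} members <= k_neighbors={k_neighbors}; "
                    f"reducing k to {k}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
            neigh_idx = nn.kneighbors(pts, return_distance=False)[:, 1:]
            base = rng.integers(0, count, n_new)
            neigh = neigh_idx[base, rng.integers(0, k, n_new)]
            u = rng.random(n_new)[:, None]
            synth = pts[base] + u * (pts[neigh] - pts[base])
        new_X.append(synth)
        new_y.append(np.full(n_new, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


def multiclass_mcc(cm: np.ndarray) -> float:
    """Gorodkin's Rk correlation from a confusion matrix.

    (N*sum_k c_kk - sum_k t_k p_k) / sqrt((N^2 - sum p_k^2)(N^2 - sum t_k^2))
    with t = row (true) sums and p = column (predicted) sums. Returns 0
    when either variance term vanishes (degenerate predictor or truth).
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix is all zero")
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    num = n * np.trace(cm) - t @ p
    d1 = n * n - p @ p
    d2 = n * n - t @ t
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return float(num / np.sqrt(d1 * d2))


def per_class_accuracy(cm: np.ndarray) -> np.ndarray:
    """Diagonal fraction per true class; NaN where a class has no samples."""
    cm = np.asarray(cm, dtype=float)
    t = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.diag(cm) / t
    return np.where(t > 0, acc, np.nan)


class OvrMaxMarginClassifier:
    """One-vs-rest linear maximum-margin classifier with calibrated scores.

    One binary linear SVM per class against the rest. Raw margins from
    different binary problems are not on a common scale, so each model's
    decision values are passed through a sigmoid (Platt-style) calibration
    fitted on the training data; prediction takes the class with the
    highest calibrated probability, ties broken by the declared class
    order. Deterministic for a fixed training set.
    """

    def __init__(self, class_names: Sequence[str] | None = None, C: float = 1.0,
                 max_iter: int = 5000):
        self.class_names = list(class_names) if class_names is not None else None
        self.C = C
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: Sequence) -> "OvrMaxMarginClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y)
        present = set(np.unique(y).tolist())
        if len(present) < 2:
            raise ValueError("training labels contain a single class")
        if self.class_names is not None:
            self.classes_ = [c for c in self.class_names if c in present]
        else:
            self.classes_ = sorted(present)
        self._models = []
        self._calibrators = []
        for c in self.classes_:
            target = (y == c).astype(int)
            clf = LinearSVC(C=self.C, dual="auto", max_iter=self.max_iter, random_state=0)
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*converge.*")
                clf.fit(X, target)
                cal = LogisticRegression(C=1e4, max_iter=1000)
                cal.fit(clf.decision_function(X).reshape(-1, 1), target)
            self._models.append(clf)
            self._calibrators.append(cal)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Calibrated per-class probabilities (columns follow ``classes_``)."""
        X = np.asarray(X, float)
        cols = []
        for m, cal in zip(self._models, self._calibrators):
            d = m.decision_function(X).reshape(-1, 1)
            cols.append(cal.predict_proba(d)[:, 1])
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        idx = np.argmax(scores, axis=1)  # first max -> declared-order tie-break
        return np.asarray([self.classes_[i] for i in idx], dtype=object)


def train_ovr_classifier(
    features: np.ndarray, labels: Sequence, class_names: Sequence[str] | None = None
) -> OvrMaxMarginClassifier:
    return OvrMaxMarginClassifier(class_names).fit(features, labels)


def _make_classifier(kind: str, class_names, marker_ids, ripper_config, seed: int):
    if kind == "svm":
        return OvrMaxMarginClassifier(class_names)
    if kind == "ripper":
        from .ruleminer import RuleLearnerConfig, RuleListClassifier

        cfg = ripper_config or RuleLearnerConfig()
        return RuleListClassifier(marker_ids, class_names, cfg, seed)
    raise ValueError(f"unknown classifier kind {kind!r}; expected 'svm' or 'ripper'")


def cross_validate(
    dataset: LabeledDataset,
    feature_subset: Sequence[str],
    classifier: str = "svm",
    smote_policy: str = "train_folds_only",
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
    stratified: bool = True,
    k_neighbors: int = 5,
    ripper_config=None,
) -> SubsetEvaluation:
    """k-fold CV of a feature subset; pooled confusion matrix, MCC, accuracies."""
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature_subset is empty")
    if smote_policy not in SMOTE_POLICIES:
        raise ValueError(f"unknown smote_policy {smote_policy!r}; expected {SMOTE_POLICIES}")
    sub = dataset.subset_features(subset)
    X = sub.signal.values
    y = sub.y
    if smote_policy == "before_split":
        X, y = smote_oversample(X, y, k_neighbors=k_neighbors, seed=_child_seed(seed, 997))
        folds = None
    if folds is None:
        if stratified:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                folds = stratified_kfold(y, k=k, seed=seed)
        else:
            kf = KFold(n_splits=k, shuffle=True, random_state=seed)
            folds = np.empty(len(y), dtype=int)
            for f, (_, test_idx) in enumerate(kf.split(np.zeros(len(y)))):
                folds[test_idx] = f
    folds = np.asarray(folds)
    if len(folds) != len(y):
        raise ValueError("fold assignment length does not match dataset")
    preds = np.empty(len(y), dtype=object)
    for f in range(int(folds.max()) + 1):
        train = folds != f
        test = ~train
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold {f}: training split contains a single class "
                f"({np.unique(y_train)[0]!r}); use fewer folds or more data"
            )
        X_train = X[train]
        if smote_policy == "train_folds_only":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                X_train, y_train = smote_oversample(
                    X_train, y_train, k_neighbors=k_neighbors, seed=_child_seed(seed, f)
                )
        clf = _make_classifier(
            classifier, dataset.class_names, sub.signal.marker_ids, ripper_config,
            _child_seed(seed, 1000 + f),
        )
        clf.fit(X_train, y_train)
        preds[test] = clf.predict(X[test])
    cm = _sk_confusion(y, preds, labels=list(dataset.class_names))
    return SubsetEvaluation(
        subset_size=len(subset),
        mcc=multiclass_mcc(cm),
        class_accuracy=per_class_accuracy(cm),
        confusion=cm,
        classifier=classifier,
        smote_policy=smote_policy,
        seed=seed,
        n_folds=int(folds.max()) + 1,
    )


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))
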