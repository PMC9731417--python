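"""Incremental top-k feature classification under stratified 10-fold CV.

Out-of-fold predictions are pooled over all folds, so the reported
correct/error counts sum to n and the accuracy equals correct/n; Cohen's
kappa corrects that accuracy for chance agreement.  The incremental curve
feeds the top-k ranked features into the classifier for k = 1..p and reports
the smallest k attaining the maximal accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .ranking import FeatureMatrix, RankingResult

__all__ = [
    "CVResult",
    "build_classifier",
    "stratified_kfold_cv",
    "cohen_kappa",
    "accuracy_from_counts",
    "incremental_curve",
    "holdout_split",
]


@dataclass
class CVResult:
    """Result of one incremental-feature cross-validated evaluation."""

    reconstruction: str
    ranker: str
    classifier: str
    curve: list[float]          # mean accuracy at k = 1..p
    best_k: int
    best_accuracy: float
    kappa: float
    correct: int
    error: int
    confusion: np.ndarray
    seed: int | None = None
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["confusion"] = self.confusion.tolist()
        return d


def build_classifier(name: str, seed: int | None = 0):
    """rf: 100-tree random forest; knn: k=5 on standardised features;
    dt: unlimited-depth Gini decision tree."""
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "knn":
        return Pipeline([("scale", StandardScaler()),
                         ("knn", KNeighborsClassifier(n_neighbors=5))])
    if name == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def stratified_kfold_cv(M: FeatureMatrix, classifier, folds: int = 10,
                        seed: int | None = 0):
    """Pooled out-of-fold metrics: (accuracy, kappa, confusion matrix).

    ``classifier`` is a name understood by :func:`build_classifier` or an
    unfitted sklearn estimator (cloned per fold).
    """
    from sklearn.base import clone
    X, y = M.values, M.labels
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        raise ValueError(f"classes too small for {folds}-fold CV: {list(small)}")
    proto = build_classifier(classifier, seed) if isinstance(classifier, str) \
        else classifier
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    for tr, te in skf.split(X, y):
        est = clone(proto)
        est.fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
    conf = confusion_matrix(y, pred, labels=classes)
    acc = float(np.trace(conf)) / y.size
    return acc, cohen_kappa(conf), conf


def cohen_kappa(confusion) -> float:
    """κ = (p_o − p_e)/(1 − p_e) from a square count table."""
    conf = np.asarray(confusion, dtype=float)
    n = conf.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(conf) / n
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0))) / n ** 2
    if p_e >= 1.0:
        import warnings
        warnings.warn("chance agreement p_e = 1; kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def accuracy_from_counts(correct: int, total: int) -> float:
    """Accuracy as a percentage, 100·correct/total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie in [0, total]")
    return 100.0 * correct / total


def incremental_curve(M: FeatureMatrix, ranking: RankingResult,
                      classifier: str = "rf", folds: int = 10,
                      seed: int | None = 0, reconstruction: str = "",
                      max_k: int | None = None) -> CVResult:
    """CV accuracy versus number of top-ranked features, k = 1..p.

    Ties on the curve resolve to the smallest k.  ``max_k`` truncates the
    sweep (the curve then has max_k entries).
    """
    p = M.p
    if sorted(ranking.order) != list(range(p)):
        raise ValueError("ranking is not a full permutation of the features")
    kmax = p if max_k is None else min(max_k, p)
    curve = []
    metrics = []
    for k in range(1, kmax + 1):
        sub = FeatureMatrix(M.values[:, ranking.order[:k]], M.labels,
                            [M.feature_names[i] for i in ranking.order[:k]])
        acc, kap, conf = stratified_kfold_cv(sub, classifier, folds, seed)
        curve.append(acc)
        metrics.append((kap, conf))
    best_k = int(np.argmax(curve)) + 1  # argmax returns the first (smallest) k
    kap, conf = metrics[best_k - 1]
    correct = int(np.trace(conf))
    return CVResult(reconstruction=reconstruction, ranker=ranking.method,
                    classifier=classifier if isinstance(classifier, str) else "custom",
                    curve=curve, best_k=best_k,
                    best_accuracy=float(curve[best_k - 1]), kappa=kap,
                    correct=correct, error=int(M.n - correct), confusion=conf,
                    seed=seed, feature_names=ranking.ordered_names()[:kmax])


def holdout_split(M: FeatureMatrix, train_fraction: float = 0.8,
                  seed: int | None = 0):
    """Stratified train/test split of a FeatureMatrix."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    idx = np.arange(M.n)
    tr, te = train_test_split(idx, train_size=train_fraction,
                              stratify=M.labels, random_state=seed)
    mk = lambda rows: FeatureMatrix(M.values[rows], M.labels[rows],
                                    list(M.feature_names))
    return mk(np.sort(tr)), mk(np.sort(te))
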