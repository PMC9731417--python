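"""Feature ranking by six methods: mRMR, KCCA-gated mRMR, QPFS, MIC,
tree-ensemble importance, and RFE with cross-validated feature count.

All rankers share the sklearn estimator shape: ``fit(X, y)`` sets
``ranking_`` (a permutation of feature indices, best first) and ``scores_``.
Mutual information uses the plug-in estimator on 10-bin equal-frequency
discretised features; score ties are broken by original feature order
(stable sorts throughout), so every ranking is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, RFECV
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureMatrix",
    "RankingResult",
    "discretize",
    "mutual_information",
    "mic_score",
    "MRMRRanker",
    "KCCAmRMRRanker",
    "QPFSRanker",
    "MICRanker",
    "TreeRanker",
    "RFECVRanker",
    "mrmr_rank",
    "kcca_mrmr_rank",
    "qpfs_rank",
    "mic_rank",
    "tree_rank",
    "rfecv_rank",
    "rank_features",
    "RANKER_NAMES",
]

MI_BINS = 10


@dataclass
class FeatureMatrix:
    """An n-by-p feature table with class labels and feature names.

    NaN cells (e.g. reserve times of records whose segmentation failed) are
    imputed with the column median at construction.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[0] != self.labels.size:
            raise ValueError("values must be n-by-p with n labels")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if np.isnan(self.values).any():
            med = np.nanmedian(self.values, axis=0)
            idx = np.where(np.isnan(self.values))
            self.values[idx] = np.take(med, idx[1])
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValueError("need >= 2 classes with >= 2 members each")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        """Build from a feature-table DataFrame with id/label columns."""
        cols = [c for c in df.columns if c not in ("id", "label")]
        return cls(values=df[cols].to_numpy(float),
                   labels=df["label"].to_numpy(), feature_names=cols)

    def subset(self, names) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], self.labels, list(names))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class RankingResult:
    """Ordered feature list (best first) with per-feature scores."""

    method: str
    order: list[int]
    scores: list[float]
    feature_names: list[str] = field(default_factory=list)
    cv_optimal_k: int | None = None

    def ordered_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.order) + 1),
            "feature": self.ordered_names(),
            "score": [self.scores[i] for i in self.order],
        })


def discretize(x, bins: int = MI_BINS) -> np.ndarray:
    """Equal-frequency binning; returns integer codes. Constant input → zeros."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return np.zeros(x.size, dtype=int)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _codes(y) -> np.ndarray:
    _, codes = np.unique(np.asarray(y), return_inverse=True)
    return codes


def mutual_information(x, y, bins: int = MI_BINS) -> float:
    """Plug-in MI (nats) between a quantile-discretised feature and labels."""
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    xd = discretize(x, bins)
    if np.ptp(xd) == 0:
        return 0.0
    return float(mutual_info_score(xd, _codes(y)))


def _mi_profiles(X: np.ndarray, y, bins: int = MI_BINS):
    """Relevance vector F and feature-feature MI matrix Q (both in nats)."""
    n, p = X.shape
    xd = [discretize(X[:, j], bins) for j in range(p)]
    yc = _codes(y)
    F = np.array([float(mutual_info_score(xd[j], yc)) for j in range(p)])
    Q = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            Q[i, j] = Q[j, i] = float(mutual_info_score(xd[i], xd[j]))
    return F, Q


def _stable_desc_order(scores: np.ndarray) -> list[int]:
    return list(np.argsort(-np.asarray(scores), kind="stable"))


class _RankerBase(BaseEstimator):
    """Shared fit plumbing: subclasses implement ``_rank(X, y)``."""

    method = "base"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        order, scores = self._rank(X, y)
        self.ranking_ = np.asarray(order, dtype=int)
        self.scores_ = np.asarray(scores, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def _rank(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError


class MRMRRanker(_RankerBase):
    """Greedy minimum-redundancy maximum-relevance ranking (MID criterion).

    Step score for a candidate f given the selected set S:
    score(f) = MI(f; y) − mean_{g in S} MI(f; g); the first pick maximises
    relevance alone.
    """

    method = "mrmr"

    def __init__(self, bins: int = MI_BINS):
        self.bins = bins

    def _redundancy(self, Q, f, selected, X, y):
        return float(np.mean(Q[f, selected]))

    def _rank(self, X, y):
        F, Q = _mi_profiles(X, y, self.bins)
        self._prepare_gate(X, y)
        p = F.size
        remaining = list(range(p))
        order, scores = [], np.zeros(p)
        while remaining:
            if not order:
                vals = [F[f] for f in remaining]
            else:
                vals = [F[f] - self._redundancy(Q, f, order, X, y)
                        for f in remaining]
            best = int(np.argmax(vals))
            f = remaining.pop(best)
            scores[f] = vals[best]
            order.append(f)
        return order, scores

    def _prepare_gate(self, X, y) -> None:
        pass


def _gaussian_gram(u: np.ndarray) -> np.ndarray:
    d2 = (u[:, None] - u[None, :]) ** 2
    pos = d2[d2 > 0]
    width2 = float(np.median(pos)) if pos.size else 1.0
    return np.exp(-d2 / (2.0 * width2))


def _kcca_first_corr(u: np.ndarray, v: np.ndarray, reg: float,
                     n_components: int = 20) -> float:
    """First canonical correlation of a low-rank regularised kernel CCA.

    Centred Gaussian Gram matrices are factorised by eigendecomposition into
    feature maps, then a ridge-regularised linear CCA runs in that space.
    """
    n = u.size
    H = np.eye(n) - np.ones((n, n)) / n

    def feature_map(w):
        K = H @ _gaussian_gram(w) @ H
        vals, vecs = np.linalg.eigh(K)
        keep = vals > max(1e-10, 1e-10 * vals.max())
        vals, vecs = vals[keep][-n_components:], vecs[:, keep][:, -n_components:]
        return vecs * np.sqrt(vals)

    Pu, Pv = feature_map(u), feature_map(v)
    Cuu = Pu.T @ Pu / n + reg * np.eye(Pu.shape[1])
    Cvv = Pv.T @ Pv / n + reg * np.eye(Pv.shape[1])
    Cuv = Pu.T @ Pv / n

    def inv_sqrt(C):
        vals, vecs = np.linalg.eigh(C)
        vals = np.clip(vals, 1e-12, None)
        return vecs @ np.diag(vals ** -0.5) @ vecs.T

    M = inv_sqrt(Cuu) @ Cuv @ inv_sqrt(Cvv)
    s = np.linalg.svd(M, compute_uv=False)
    return float(np.clip(s[0] if s.size else 0.0, 0.0, 1.0))


class KCCAmRMRRanker(MRMRRanker):
    """mRMR counting only label-relevant redundancy.

    The redundancy term MI(f; g) is zeroed when the kernel canonical
    correlation between the label-explained components E[f|y] and E[g|y],
    scaled by how much label-explained variance each feature carries
    (sqrt of the two R² ratios), falls below ``gate_threshold``: dependence
    that the class variable does not mediate is then ignored, so noise-driven
    co-variation no longer penalises a candidate.  As reg → ∞ every canonical
    correlation collapses and the ranking degenerates to relevance-only.
    """

    method = "kcca_mrmr"

    def __init__(self, bins: int = MI_BINS, reg: float = 0.1,
                 gate_threshold: float = 0.3, max_gate_samples: int = 200,
                 random_state: int | None = 0):
        self.bins = bins
        self.reg = reg
        self.gate_threshold = gate_threshold
        self.max_gate_samples = max_gate_samples
        self.random_state = random_state

    def _prepare_gate(self, X, y) -> None:
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        idx = (rng.permutation(n)[: self.max_gate_samples]
               if n > self.max_gate_samples else np.arange(n))
        Xs, ys = X[idx], _codes(y)[idx]
        p = X.shape[1]
        cond_mean = np.empty_like(Xs)
        r2 = np.zeros(p)
        for j in range(p):
            col = Xs[:, j]
            fitted = np.empty_like(col)
            for c in np.unique(ys):
                m = ys == c
                fitted[m] = col[m].mean()
            cond_mean[:, j] = fitted
            var = col.var()
            r2[j] = fitted.var() / var if var > 0 else 0.0
        self._gate_cond_mean = cond_mean
        self._gate_r2 = r2
        self._gate_cache: dict[tuple[int, int], float] = {}

    def _gate(self, f: int, g: int) -> float:
        key = (min(f, g), max(f, g))
        if key not in self._gate_cache:
            rho = _kcca_first_corr(self._gate_cond_mean[:, f],
                                   self._gate_cond_mean[:, g], self.reg)
            self._gate_cache[key] = rho * float(
                np.sqrt(self._gate_r2[f] * self._gate_r2[g]))
        return self._gate_cache[key]

    def _redundancy(self, Q, f, selected, X, y):
        terms = [Q[f, g] if self._gate(f, g) >= self.gate_threshold else 0.0
                 for g in selected]
        return float(np.mean(terms))


class QPFSRanker(_RankerBase):
    """Quadratic-programming feature selection.

    Solves min_w ½(1−α)·wᵀQw − α·Fᵀw on the probability simplex, with Q the
    feature-feature MI similarity matrix, F the feature-label MI vector and
    α = mean(Q)/(mean(Q)+mean(F)); features rank by descending weight.
    """

    method = "qpfs"

    def __init__(self, bins: int = MI_BINS, tol: float = 1e-12):
        self.bins = bins
        self.tol = tol

    def _rank(self, X, y):
        F, Q = _mi_profiles(X, y, self.bins)
        p = F.size
        mq, mf = float(np.mean(Q)), float(np.mean(F))
        alpha = mq / (mq + mf) if (mq + mf) > 0 else 0.5
        A = (1.0 - alpha) * Q

        def obj(w):
            return 0.5 * w @ A @ w - alpha * F @ w

        def jac(w):
            return A @ w - alpha * F

        w0 = np.full(p, 1.0 / p)
        res = minimize(obj, w0, jac=jac, method="SLSQP",
                       bounds=[(0.0, 1.0)] * p,
                       constraints=[{"type": "eq",
                                     "fun": lambda w: np.sum(w) - 1.0,
                                     "jac": lambda w: np.ones(p)}],
                       options={"maxiter": 1000, "ftol": self.tol})
        if not res.success:
            raise RuntimeError(f"QPFS solver failed: {res.message}")
        w = np.clip(res.x, 0.0, None)
        w = w / w.sum()
        self.weights_ = w
        self.alpha_ = alpha
        return _stable_desc_order(w), w


def mic_score(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of a feature against class labels.

    Equipartition-grid approximation of MINE: the feature axis is cut into a
    equal-frequency bins, the label axis into b contiguous groups of class
    codes, over all grids with a·b ≤ B = n^alpha (and a ≤ c·b); the score is
    max over grids of I(a-binned x; b-grouped y) / log min(a, b) ∈ [0, 1].
    """
    x = np.asarray(x, dtype=float)
    yc = _codes(y)
    n = x.size
    k = int(yc.max()) + 1
    B = max(n ** alpha, 4.0)
    best = 0.0
    from itertools import combinations
    for b in range(2, k + 1):
        # contiguous groupings of the k class codes into b groups
        for cuts in combinations(range(1, k), b - 1):
            bounds = (0,) + cuts + (k,)
            yg = np.zeros(n, dtype=int)
            for gi in range(b):
                yg[(yc >= bounds[gi]) & (yc < bounds[gi + 1])] = gi
            a_max = min(int(B // b), c * b)
            for a in range(2, max(a_max, 2) + 1):
                if a * b > B:
                    break
                xd = discretize(x, a)
                if np.ptp(xd) == 0:
                    continue
                i_ab = float(mutual_info_score(xd, yg))
                denom = np.log(min(a, len(np.unique(yg))))
                if denom > 0:
                    best = max(best, i_ab / denom)
    return float(min(best, 1.0))


class MICRanker(_RankerBase):
    """Rank by per-feature MIC against the class labels."""

    method = "mic"

    def __init__(self, alpha: float = 0.6, c: int = 15):
        self.alpha = alpha
        self.c = c

    def _rank(self, X, y):
        scores = np.array([mic_score(X[:, j], y, self.alpha, self.c)
                           for j in range(X.shape[1])])
        return _stable_desc_order(scores), scores


class TreeRanker(_RankerBase):
    """Mean impurity-decrease importance from a randomised tree ensemble."""

    method = "tree"

    def __init__(self, n_trees: int = 200, random_state: int | None = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def _rank(self, X, y):
        forest = RandomForestClassifier(n_estimators=self.n_trees,
                                        random_state=self.random_state,
                                        n_jobs=1)
        forest.fit(X, y)
        imp = forest.feature_importances_
        return _stable_desc_order(imp), imp


class RFECVRanker(_RankerBase):
    """Recursive feature elimination (one feature per step) with a CV-chosen
    feature count; elimination order reversed gives the full ranking."""

    method = "rfecv"

    def __init__(self, folds: int = 10, n_trees: int = 100,
                 random_state: int | None = 0):
        self.folds = folds
        self.n_trees = n_trees
        self.random_state = random_state

    def _rank(self, X, y):
        est = RandomForestClassifier(n_estimators=self.n_trees,
                                     random_state=self.random_state, n_jobs=1)
        rfe = RFE(est, n_features_to_select=1, step=1).fit(X, y)
        order = list(np.argsort(rfe.ranking_, kind="stable"))
        cv = StratifiedKFold(self.folds, shuffle=True,
                             random_state=self.random_state)
        rfecv = RFECV(est, step=1, cv=cv, n_jobs=1).fit(X, y)
        self.cv_optimal_k_ = int(rfecv.n_features_)
        scores = (X.shape[1] - rfe.ranking_).astype(float)
        return order, scores


def _as_result(ranker, M: FeatureMatrix) -> RankingResult:
    ranker.fit(M.values, M.labels)
    return RankingResult(method=ranker.method,
                         order=list(ranker.ranking_),
                         scores=list(ranker.scores_),
                         feature_names=list(M.feature_names),
                         cv_optimal_k=getattr(ranker, "cv_optimal_k_", None))


def mrmr_rank(M: FeatureMatrix) -> RankingResult:
    return _as_result(MRMRRanker(), M)


def kcca_mrmr_rank(M: FeatureMatrix, kernel_width: float | None = None,
                   reg: float = 0.1) -> RankingResult:
    return _as_result(KCCAmRMRRanker(reg=reg), M)


def qpfs_rank(M: FeatureMatrix) -> RankingResult:
    return _as_result(QPFSRanker(), M)


def mic_rank(M: FeatureMatrix) -> RankingResult:
    return _as_result(MICRanker(), M)


def tree_rank(M: FeatureMatrix, n_trees: int = 200, seed: int | None = 0) -> RankingResult:
    return _as_result(TreeRanker(n_trees=n_trees, random_state=seed), M)


def rfecv_rank(M: FeatureMatrix, folds: int = 10, seed: int | None = 0) -> RankingResult:
    return _as_result(RFECVRanker(folds=folds, random_state=seed), M)


RANKER_NAMES = ("mrmr", "kcca_mrmr", "qpfs", "mic", "tree", "rfecv")


def rank_features(M: FeatureMatrix, method: str, seed: int | None = 0) -> RankingResult:
    """Dispatch to one of the six ranking methods by name."""
    if method == "mrmr":
        return mrmr_rank(M)
    if method == "kcca_mrmr":
        return _as_result(KCCAmRMRRanker(random_state=seed), M)
    if method == "qpfs":
        return qpfs_rank(M)
    if method == "mic":
        return mic_rank(M)
    if method == "tree":
        return tree_rank(M, seed=seed)
    if method == "rfecv":
        return rfecv_rank(M, seed=seed)
    raise ValueError(f"unknown ranking method {method!r}")
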