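"""Reproducible study routines behind the package's headline checks.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns plain numbers, so the same code backs both the
test suite and the reproduction script.  Problem sizes are the package's
defaults for a desk-scale study: 1.5 s records for the classification
corpora, 3 s records for segmentation recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .emd import decompose
from .errors import SegmentationError
from .evaluation import incremental_curve, stratified_kfold_cv
from .pipeline import build_feature_matrix
from .ranking import FeatureMatrix, tree_rank
from .segmentation import reserve_times, segment
from .synth import SynthSpec, default_class_specs, generate, generate_corpus

__all__ = [
    "emd_completeness_study",
    "two_tone_study",
    "segmentation_recovery_study",
    "end_to_end_study",
    "snr_robustness_study",
    "canonical_feature_table",
    "informative_above_noise",
    "ranking_sanity_study",
]


def emd_completeness_study(n_signals: int = 100, seed: int = 0) -> dict:
    """Max relative reconstruction error of EMD over random signals."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_signals):
        n = int(rng.integers(500, 5001))
        kind = rng.integers(0, 3)
        if kind == 0:
            x = rng.standard_normal(n)
        elif kind == 1:
            x = rng.standard_normal(n).cumsum()
        else:
            t = np.arange(n) / 2205.0
            x = (np.sin(2 * np.pi * rng.uniform(20, 300) * t)
                 + 0.5 * rng.standard_normal(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            im = decompose(x)
        err = float(np.linalg.norm(x - im.reconstruct_full())
                    / np.linalg.norm(x))
        worst = max(worst, err)
    return {"max_rel_error": worst, "n": n_signals}


def two_tone_study(fs: float = 2205.0, duration: float = 1.0) -> dict:
    """Correlations of the separated tones with their EMD layers."""
    t = np.arange(int(fs * duration)) / fs
    hi = np.sin(2 * np.pi * 300 * t)
    lo = np.sin(2 * np.pi * 30 * t)
    im = decompose(hi + lo)
    c_hi = float(np.corrcoef(im.imfs[0], hi)[0, 1])
    c_lo = max(float(np.corrcoef(im.imfs[i], lo)[0, 1])
               for i in range(1, len(im)))
    return {"c1_vs_300Hz": c_hi, "best_later_vs_30Hz": c_lo, "n": t.size}


def segmentation_recovery_study(n_trials: int = 100, seed: int = 0,
                                tol: float = 0.010) -> dict:
    """Fraction of synthetic PCGs whose four reserve times are recovered
    within ``tol`` seconds of generator truth (50-140 bpm, SNR >= 10 dB)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trials):
        spec = SynthSpec(heart_rate=float(rng.uniform(50, 140)),
                         snr=float(rng.uniform(10, 30)), duration=3.0,
                         seed=int(rng.integers(2 ** 31)))
        rec, truth, _ = generate(spec)
        want = reserve_times(truth)
        try:
            got = reserve_times(segment(rec.samples, rec.fs))
        except SegmentationError:
            continue
        errs = [abs(got.T1 - want.T1), abs(got.T2 - want.T2),
                abs(got.T11 - want.T11), abs(got.T12 - want.T12)]
        if max(errs) <= tol:
            hits += 1
    return {"recovery_rate": hits / n_trials, "n": n_trials}


INFORMATIVE_GROUPS = ({0, 3}, {1, 4}, {2})   # feature-index groups per signal
NOISE_FEATURES = frozenset(range(5, 10))


def canonical_feature_table(n: int = 500, seed: int = 0) -> FeatureMatrix:
    """The canonical ranking benchmark: 3 informative features (class-shifted
    Gaussians), 2 exact redundant copies, 5 pure-noise features, 5 classes."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(5), n // 5)[rng.permutation(n)]
    cols = []
    for _ in range(3):
        shifts = rng.permutation(5) * 2.0
        cols.append(shifts[y] + rng.standard_normal(n) * 0.5)
    cols.append(cols[0].copy())
    cols.append(cols[1].copy())
    for _ in range(5):
        cols.append(rng.standard_normal(n))
    names = (["inf1", "inf2", "inf3", "copy1", "copy2"]
             + [f"noise{i}" for i in range(5)])
    return FeatureMatrix(np.column_stack(cols),
                         np.array([f"C{c}" for c in y]), names)


def informative_above_noise(order) -> bool:
    """Does each informative signal's best representative outrank all noise?"""
    pos = {f: i for i, f in enumerate(order)}
    best_noise = min(pos[f] for f in NOISE_FEATURES)
    return all(min(pos[f] for f in g) < best_noise
               for g in INFORMATIVE_GROUPS)


def ranking_sanity_study(seed: int = 0, n: int = 500) -> dict:
    """How many of the six rankers keep informative features above noise."""
    from .ranking import RANKER_NAMES, rank_features
    M = canonical_feature_table(n=n, seed=seed)
    ok = sum(informative_above_noise(rank_features(M, m, seed=seed).order)
             for m in RANKER_NAMES)
    return {"rankers_passing": ok, "n_rankers": len(RANKER_NAMES), "n": n}


def _corpus_matrix(n_per_class: int, snr: float, duration: float, seed: int,
                   method: str, include_reserve: bool = True) -> FeatureMatrix:
    specs = default_class_specs(snr=snr, duration=duration)
    records, _, _ = generate_corpus(specs, n_per_class, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_matrix(records, method=method,
                                    include_reserve=include_reserve)


def end_to_end_study(n_per_class: int = 100, snr: float = 15.0,
                     duration: float = 1.5, seed: int = 0) -> dict:
    """Adaptive-HD + fused features + tree ranking + RF, 10-fold CV.

    Returns the best accuracy over the incremental top-k curve for the
    40-feature table and for its 36-feature reduction (reserve times
    dropped), plus the feature count attaining each.
    """
    M40 = _corpus_matrix(n_per_class, snr, duration, seed, "adaptive_hd")
    keep36 = [n for n in M40.feature_names if n not in ("T1", "T2", "T11", "T12")]
    M36 = M40.subset(keep36)
    out = {}
    for tag, M in (("40", M40), ("36", M36)):
        ranking = tree_rank(M, seed=seed)
        cv = incremental_curve(M, ranking, classifier="rf", folds=10, seed=seed)
        out[f"best_accuracy_{tag}"] = cv.best_accuracy
        out[f"best_k_{tag}"] = cv.best_k
        out[f"kappa_{tag}"] = cv.kappa
    out["n"] = M40.n
    return out


def snr_robustness_study(n_per_class: int = 20, snr: float = 0.0,
                         duration: float = 1.5, n_seeds: int = 5,
                         base_seed: int = 0) -> dict:
    """Median 10-fold CV accuracy (full 40 features) of adaptive-HD
    reconstruction versus no reconstruction on matched noisy corpora."""
    acc_hd, acc_none = [], []
    for k in range(n_seeds):
        seed = base_seed + 1000 + k
        M_hd = _corpus_matrix(n_per_class, snr, duration, seed, "adaptive_hd")
        M_no = _corpus_matrix(n_per_class, snr, duration, seed, "none")
        a_hd, _, _ = stratified_kfold_cv(M_hd, "rf", folds=10, seed=seed)
        a_no, _, _ = stratified_kfold_cv(M_no, "rf", folds=10, seed=seed)
        acc_hd.append(a_hd)
        acc_none.append(a_no)
    return {"adaptive_hd_accuracy": float(np.median(acc_hd)),
            "no_emd_accuracy": float(np.median(acc_none)),
            "n": n_per_class * 5 * n_seeds}
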