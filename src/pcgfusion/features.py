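"""The 40-dimensional fused feature vector.

Four feature families are computed from one (reconstructed) heart-sound
signal: 4 cardiac reserve times (T1, T2, T11, T12, from segmentation),
21 time-domain statistics, 11 frequency-domain quantities (DFT magnitude
spectrum and analytic-signal instantaneous quantities), and 4 nonlinear
entropies.  Conventions that the source material leaves open:

* population (1/N) moment normalisation; kurtosis is non-excess (Gaussian→3);
* X_peak = max|x| for the crest/impulse/margin factors; peak-to-peak is its
  own feature max − min;
* form factor is E[X²]/E[|X|] (the printed formula of the feature table);
* quartiles by linear interpolation between order statistics (type 7);
* energy entropy = Shannon entropy (nats) of 20 ms frame-energy fractions;
* spectral Shannon entropy over the normalised power spectrum;
* instantaneous frequency from the central-difference derivative of the
  unwrapped analytic phase, negative values clipped to zero, record edges
  trimmed;
* sample/approximate entropy with m = 2, r = 0.2·SD (Chebyshev metric,
  counted with a k-d tree);
* multiscale permutation entropy: order 3, delay 1, scales 1–5, normalised
  per scale by log 3! and averaged;
* exponential entropy in the Pal–Pal form Σ p·e^(1−p) − 1 over the 20 ms
  frame-energy distribution.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
from scipy.signal import hilbert
from scipy.spatial import cKDTree

from .errors import DegenerateSignalError
from .segmentation import CycleSegmentation, ReserveTimes, reserve_times

__all__ = [
    "FEATURE_NAMES",
    "RESERVE_NAMES",
    "time_features",
    "frequency_features",
    "nonlinear_features",
    "sample_entropy",
    "approximate_entropy",
    "permutation_entropy",
    "multiscale_permutation_entropy",
    "extract_all",
]

RESERVE_NAMES = ("T1", "T2", "T11", "T12")

TIME_NAMES = (
    "mean", "mean_square", "max", "min", "variance", "std", "rms",
    "peak_to_peak", "root_square_amplitude", "skewness", "kurtosis",
    "form_factor", "crest_factor", "impulse_factor", "margin_factor",
    "hjorth_mobility", "hjorth_complexity", "q1", "q2", "q3", "iqr",
)

NONLINEAR_NAMES = (
    "sample_entropy", "approximate_entropy", "mspe", "exponential_entropy",
)

FREQ_NAMES = (
    "energy_entropy", "shannon_entropy", "mean_square_frequency",
    "centroid_frequency", "rms_frequency", "frequency_std",
    "inst_energy_maxmin_dev", "inst_energy_median", "inst_energy_mean",
    "inst_freq_median", "inst_freq_mean",
)

# Table order: reserve times, time domain, then the interleaved
# entropy/frequency block as listed in the fused-feature table.
FEATURE_NAMES = (
    "T1", "T2", "T11", "T12",
    "mean", "mean_square", "max", "min", "variance", "std", "rms",
    "peak_to_peak", "root_square_amplitude", "skewness", "kurtosis",
    "form_factor", "crest_factor", "impulse_factor", "margin_factor",
    "hjorth_mobility", "hjorth_complexity", "q1", "q2", "q3", "iqr",
    "energy_entropy", "sample_entropy", "approximate_entropy",
    "shannon_entropy", "mspe", "exponential_entropy",
    "mean_square_frequency", "centroid_frequency", "rms_frequency",
    "frequency_std", "inst_energy_maxmin_dev", "inst_energy_median",
    "inst_energy_mean", "inst_freq_median", "inst_freq_mean",
)

FRAME_SEC = 0.020  # frame length for energy-distribution entropies


def time_features(x) -> dict[str, float]:
    """The 21 time-domain statistics (population normalisation throughout)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DegenerateSignalError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant signal: shape factors undefined")
    mu = float(np.mean(x))
    ms = float(np.mean(x ** 2))
    var = float(np.mean((x - mu) ** 2))
    sd = math.sqrt(var)
    rms_ = math.sqrt(ms)
    mx, mn = float(np.max(x)), float(np.min(x))
    abs_mean = float(np.mean(np.abs(x)))
    x_rm = float(np.mean(np.sqrt(np.abs(x)))) ** 2
    x_peak = float(np.max(np.abs(x)))
    mu3 = float(np.mean((x - mu) ** 3))
    mu4 = float(np.mean((x - mu) ** 4))
    dx = np.diff(x)
    var_d = float(np.var(dx))
    mobility = math.sqrt(var_d / var)
    ddx = np.diff(dx)
    var_dd = float(np.var(ddx))
    mob_d = math.sqrt(var_dd / var_d) if var_d > 0 else 0.0
    complexity = mob_d / mobility if mobility > 0 else 0.0
    q1, q2, q3 = (float(q) for q in np.percentile(x, [25, 50, 75]))
    return {
        "mean": mu,
        "mean_square": ms,
        "max": mx,
        "min": mn,
        "variance": var,
        "std": sd,
        "rms": rms_,
        "peak_to_peak": mx - mn,
        "root_square_amplitude": x_rm,
        "skewness": mu3 / sd ** 3,
        "kurtosis": mu4 / sd ** 4,
        "form_factor": ms / abs_mean,
        "crest_factor": x_peak / rms_,
        "impulse_factor": x_peak / abs_mean,
        "margin_factor": x_peak / x_rm,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "q1": q1,
        "q2": q2,
        "q3": q3,
        "iqr": q3 - q1,
    }


def _frame_energies(x: np.ndarray, fs: float) -> np.ndarray:
    frame = max(1, int(round(FRAME_SEC * fs)))
    n_frames = x.size // frame
    if n_frames < 1:
        return np.array([float(np.sum(x ** 2))])
    e = np.sum(x[: n_frames * frame].reshape(n_frames, frame) ** 2, axis=1)
    return e


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def frequency_features(x, fs: float) -> dict[str, float]:
    """The 11 spectral and analytic-signal features."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise DegenerateSignalError("need at least 16 samples")
    if np.max(np.abs(x)) == 0:
        raise DegenerateSignalError("all-zero signal")

    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    w = mag / np.sum(mag)
    centroid = float(np.sum(freqs * w))
    msf = float(np.sum(freqs ** 2 * w))
    fstd = float(np.sqrt(np.sum((freqs - centroid) ** 2 * w)))

    power = mag ** 2
    p_spec = power / np.sum(power)
    shannon_ent = _shannon(p_spec)

    e = _frame_energies(x, fs)
    p_e = e / np.sum(e) if np.sum(e) > 0 else np.ones_like(e) / e.size
    energy_ent = _shannon(p_e)

    analytic = hilbert(x)
    inst_energy = np.abs(analytic) ** 2
    phase = np.unwrap(np.angle(analytic))
    inst_freq = np.gradient(phase) * fs / (2 * np.pi)
    trim = min(5, x.size // 4)
    inst_freq = np.clip(inst_freq[trim: x.size - trim], 0.0, None)
    ie = inst_energy[trim: x.size - trim]

    return {
        "energy_entropy": energy_ent,
        "shannon_entropy": shannon_ent,
        "mean_square_frequency": msf,
        "centroid_frequency": centroid,
        "rms_frequency": math.sqrt(msf),
        "frequency_std": fstd,
        "inst_energy_maxmin_dev": float(np.max(ie) - np.min(ie)),
        "inst_energy_median": float(np.median(ie)),
        "inst_energy_mean": float(np.mean(ie)),
        "inst_freq_median": float(np.median(inst_freq)),
        "inst_freq_mean": float(np.mean(inst_freq)),
    }


def _embed_count_pairs(x: np.ndarray, m: int, r: float) -> int:
    """Unordered template pairs (i<j) of length-m vectors within Chebyshev r."""
    nvec = x.size - m + 1
    X = np.lib.stride_tricks.sliding_window_view(x, m)
    tree = cKDTree(X)
    total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs incl. self
    return (int(total) - nvec) // 2


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Richman–Moorman sample entropy; constant input → 0 by convention."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise DegenerateSignalError("signal too short for sample entropy")
    sd = float(np.std(x))
    if sd == 0:
        warnings.warn("constant signal: sample entropy defined as 0", stacklevel=2)
        return 0.0
    if r is None:
        r = 0.2 * sd
    # restrict length-m templates to the first N-m so both counts average
    # over the same number of templates
    b = _embed_count_pairs(x[:-1], m, r)
    a = _embed_count_pairs(x, m + 1, r)
    if a == 0 or b == 0:
        # no matching templates at one length: entropy is undefined; report 0
        # (the degenerate convention) rather than an infinity
        warnings.warn("sample entropy degenerate (no template matches)", stacklevel=2)
        return 0.0
    return float(-np.log(a / b))


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy (self-matches included)."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise DegenerateSignalError("signal too short for approximate entropy")
    sd = float(np.std(x))
    if sd == 0:
        warnings.warn("constant signal: approximate entropy defined as 0", stacklevel=2)
        return 0.0
    if r is None:
        r = 0.2 * sd

    def phi(mm: int) -> float:
        X = np.lib.stride_tricks.sliding_window_view(x, mm)
        tree = cKDTree(X)
        counts = tree.query_ball_point(X, r, p=np.inf, return_length=True)
        return float(np.mean(np.log(counts / X.shape[0])))

    return phi(m) - phi(m + 1)


def permutation_entropy(x, order: int = 3, delay: int = 1,
                        normalize: bool = True) -> float:
    """Bandt–Pompe permutation entropy over ordinal patterns."""
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        raise DegenerateSignalError("signal too short for permutation entropy")
    cols = [x[i * delay: i * delay + n] for i in range(order)]
    emb = np.column_stack(cols)
    patterns = np.argsort(emb, axis=1, kind="stable")
    # encode each pattern as an integer
    codes = np.zeros(n, dtype=np.int64)
    for k in range(order):
        codes = codes * order + patterns[:, k]
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n
    h = _shannon(p)
    if normalize:
        h /= math.log(math.factorial(order))
    return float(h)


def multiscale_permutation_entropy(x, order: int = 3, delay: int = 1,
                                   scales: int = 5) -> float:
    """Mean normalised permutation entropy over coarse-graining scales 1..scales."""
    x = np.asarray(x, dtype=float)
    vals = []
    for s in range(1, scales + 1):
        n = x.size // s
        coarse = x[: n * s].reshape(n, s).mean(axis=1) if s > 1 else x
        vals.append(permutation_entropy(coarse, order, delay))
    return float(np.mean(vals))


def exponential_entropy(x, fs: float) -> float:
    """Pal–Pal exponential entropy Σ p·e^(1−p) − 1 over frame energies."""
    x = np.asarray(x, dtype=float)
    e = _frame_energies(x, fs)
    tot = np.sum(e)
    if tot <= 0:
        return 0.0
    p = e / tot
    return float(np.sum(p * np.exp(1.0 - p)) - 1.0)


def nonlinear_features(x, fs: float = 2205.0) -> dict[str, float]:
    """Sample, approximate, multiscale-permutation and exponential entropy."""
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise DegenerateSignalError("need at least 100 samples")
    if np.ptp(x) == 0:
        warnings.warn("constant signal: entropies defined as 0", stacklevel=2)
        return {name: 0.0 for name in NONLINEAR_NAMES}
    return {
        "sample_entropy": sample_entropy(x),
        "approximate_entropy": approximate_entropy(x),
        "mspe": multiscale_permutation_entropy(x),
        "exponential_entropy": exponential_entropy(x, fs),
    }


def extract_all(x, fs: float, seg: CycleSegmentation | None = None,
                include_reserve: bool = True) -> dict[str, float]:
    """The fused feature vector, in the canonical feature-table order.

    With ``include_reserve`` the vector has 40 entries; reserve times come
    from ``seg`` (NaN placeholders when segmentation failed — imputed later
    at the dataset level).  Without it the 36-feature variant drops
    T1/T2/T11/T12.
    """
    x = np.asarray(x, dtype=float)
    feats: dict[str, float] = {}
    if include_reserve:
        if seg is not None:
            rt: ReserveTimes = reserve_times(seg)
            feats.update(rt.as_dict())
        else:
            feats.update({name: float("nan") for name in RESERVE_NAMES})
    feats.update(time_features(x))
    tmp = {}
    tmp.update(nonlinear_features(x, fs))
    tmp.update(frequency_features(x, fs))
    order = FEATURE_NAMES if include_reserve else FEATURE_NAMES[4:]
    out = {}
    for name in order:
        out[name] = feats[name] if name in feats else tmp[name]
    return out
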