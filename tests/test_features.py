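import math
import warnings

import numpy as np
import pytest

from pcgfusion import (extract_all, frequency_features, nonlinear_features,
                       time_features)
from pcgfusion.errors import DegenerateSignalError
from pcgfusion.features import (FEATURE_NAMES, approximate_entropy,
                                multiscale_permutation_entropy,
                                permutation_entropy, sample_entropy)

FS = 2205.0


def brute_force_time_features(x):
    """Direct-sum evaluation of every time-domain statistic."""
    x = np.asarray(x, float)
    n = x.size
    mu = sum(x) / n
    ms = sum(v * v for v in x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    rms = math.sqrt(ms)
    amean = sum(abs(v) for v in x) / n
    xrm = (sum(math.sqrt(abs(v)) for v in x) / n) ** 2
    xpk = max(abs(v) for v in x)
    mu3 = sum((v - mu) ** 3 for v in x) / n
    mu4 = sum((v - mu) ** 4 for v in x) / n
    s = sorted(x)

    def quant(q):
        h = (n - 1) * q
        lo = math.floor(h)
        return s[lo] + (h - lo) * (s[min(lo + 1, n - 1)] - s[lo])

    dx = np.diff(x)
    mob = math.sqrt(np.var(dx) / var)
    mob_d = math.sqrt(np.var(np.diff(dx)) / np.var(dx))
    return {
        "mean": mu, "mean_square": ms, "max": max(x), "min": min(x),
        "variance": var, "std": sd, "rms": rms,
        "peak_to_peak": max(x) - min(x), "root_square_amplitude": xrm,
        "skewness": mu3 / sd ** 3, "kurtosis": mu4 / sd ** 4,
        "form_factor": ms / amean, "crest_factor": xpk / rms,
        "impulse_factor": xpk / amean, "margin_factor": xpk / xrm,
        "hjorth_mobility": mob, "hjorth_complexity": mob_d / mob,
        "q1": quant(0.25), "q2": quant(0.5), "q3": quant(0.75),
        "iqr": quant(0.75) - quant(0.25),
    }


class TestTimeFeatures:
    def test_tiny_example(self):
        tf = time_features([1.0, 2.0, 3.0])
        assert tf["mean"] == 2.0
        assert tf["variance"] == pytest.approx(2 / 3)
        assert tf["max"] == 3.0 and tf["min"] == 1.0
        assert tf["peak_to_peak"] == 2.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(rng.integers(20, 400))) * rng.uniform(0.1, 5)
        got = time_features(x)
        want = brute_force_time_features(x)
        for name, v in want.items():
            assert got[name] == pytest.approx(v, rel=1e-9), name

    def test_gaussian_skewness_and_kurtosis(self):
        g = np.random.default_rng(0).standard_normal(10 ** 5)
        tf = time_features(g)
        assert abs(tf["skewness"]) < 0.05
        assert abs(tf["kurtosis"] - 3.0) < 0.1   # non-excess convention

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            time_features(np.full(100, 3.0))

    def test_scale_equivariance(self):
        x = np.random.default_rng(1).standard_normal(1000)
        a, b = time_features(x), time_features(2 * x)
        for name in ("max", "min", "rms", "peak_to_peak"):
            assert b[name] == pytest.approx(2 * a[name], rel=1e-9)
        assert b["variance"] == pytest.approx(4 * a["variance"], rel=1e-9)
        for name in ("skewness", "kurtosis", "form_factor", "crest_factor",
                     "impulse_factor", "margin_factor", "hjorth_mobility",
                     "hjorth_complexity"):
            if name == "form_factor":
                continue  # E[X^2]/E[|X|] scales linearly by construction
            assert b[name] == pytest.approx(a[name], rel=1e-9), name


class TestFrequencyFeatures:
    def test_pure_tone_centroid_and_inst_freq(self):
        t = np.arange(int(FS)) / FS
        ff = frequency_features(np.sin(2 * np.pi * 100 * t), FS)
        assert abs(ff["centroid_frequency"] - 100) < 1.0
        assert abs(ff["inst_freq_mean"] - 100) < 1.0
        assert abs(ff["inst_freq_median"] - 100) < 1.0

    def test_white_noise_centroid_near_quarter_fs(self):
        x = np.random.default_rng(0).standard_normal(int(4 * FS))
        ff = frequency_features(x, FS)
        assert abs(ff["centroid_frequency"] - FS / 4) < 0.05 * FS / 4

    def test_centroid_within_nyquist(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.standard_normal(500)
            ff = frequency_features(x, FS)
            assert 0 <= ff["centroid_frequency"] <= FS / 2

    def test_rms_frequency_consistency(self):
        x = np.random.default_rng(2).standard_normal(2048)
        ff = frequency_features(x, FS)
        assert ff["rms_frequency"] == pytest.approx(
            math.sqrt(ff["mean_square_frequency"]))

    def test_spectral_entropy_extremes(self):
        t = np.arange(1024) / FS
        # single-bin spectrum: one exact DFT bin frequency
        f0 = 32 * FS / 1024
        ff = frequency_features(np.sin(2 * np.pi * f0 * t), FS)
        assert ff["shannon_entropy"] < 0.1
        # exactly flat spectrum: a unit impulse
        x = np.zeros(1024)
        x[0] = 1.0
        ff = frequency_features(x, FS)
        assert ff["shannon_entropy"] == pytest.approx(math.log(513), rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSignalError):
            frequency_features(np.zeros(100), FS)


def sample_entropy_brute(x, m=2, r=None):
    """Direct O(N^2) pairwise-count evaluation of sample entropy."""
    x = np.asarray(x, float)
    r = 0.2 * np.std(x) if r is None else r
    N = x.size

    def pairs(mm):
        X = np.lib.stride_tricks.sliding_window_view(x, mm)[: N - m]
        total = 0
        for i in range(X.shape[0]):
            d = np.max(np.abs(X[i + 1:] - X[i]), axis=1)
            total += int(np.sum(d <= r))
        return total

    b, a = pairs(m), pairs(m + 1)
    return -math.log(a / b)


class TestNonlinearFeatures:
    def test_sample_entropy_matches_brute_force(self):
        u = np.random.default_rng(0).uniform(size=10 ** 4)
        assert sample_entropy(u) == pytest.approx(sample_entropy_brute(u),
                                                  abs=0.15)

    def test_sample_entropy_brute_exact_small(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal(300)
            assert sample_entropy(x) == pytest.approx(
                sample_entropy_brute(x), rel=1e-12)

    def test_constant_entropies_are_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert sample_entropy(np.ones(300)) == 0.0
            out = nonlinear_features(np.ones(300))
        assert all(v == 0.0 for v in out.values())

    def test_monotone_permutation_entropy_zero(self):
        assert permutation_entropy(np.arange(500.0)) == 0.0
        assert multiscale_permutation_entropy(np.arange(500.0)) == 0.0

    def test_random_sequence_permutation_entropy_near_max(self):
        x = np.random.default_rng(1).standard_normal(10 ** 4)
        assert permutation_entropy(x) > 0.95   # normalised by log 3!

    def test_approximate_entropy_regular_vs_random(self):
        t = np.arange(2000) / FS
        regular = np.sin(2 * np.pi * 25 * t)
        random_ = np.random.default_rng(2).standard_normal(2000)
        assert approximate_entropy(regular) < approximate_entropy(random_)

    def test_entropies_scale_invariant(self):
        x = np.random.default_rng(4).standard_normal(2000)
        a = nonlinear_features(x)
        b = nonlinear_features(5 * x)
        assert b["sample_entropy"] == pytest.approx(a["sample_entropy"], rel=1e-9)
        assert b["mspe"] == pytest.approx(a["mspe"], rel=1e-9)


@pytest.fixture(scope="module")
def signal():
    t = np.arange(int(2 * FS)) / FS
    rng = np.random.default_rng(0)
    return np.sin(2 * np.pi * 40 * t) + 0.1 * rng.standard_normal(t.size)


class TestExtractAll:
    def test_forty_features_in_table_order(self, signal):
        feats = extract_all(signal, FS, seg=None, include_reserve=True)
        assert list(feats) == list(FEATURE_NAMES)
        assert len(feats) == 40

    def test_thirty_six_variant_drops_reserve_times(self, signal):
        feats = extract_all(signal, FS, include_reserve=False)
        assert len(feats) == 36
        assert not {"T1", "T2", "T11", "T12"} & set(feats)

    def test_missing_segmentation_yields_nan_reserve(self, signal):
        feats = extract_all(signal, FS, seg=None, include_reserve=True)
        assert all(math.isnan(feats[n]) for n in ("T1", "T2", "T11", "T12"))
        rest = [v for k, v in feats.items() if k not in ("T1", "T2", "T11", "T12")]
        assert np.all(np.isfinite(rest))

    def test_deterministic(self, signal):
        a = extract_all(signal, FS, include_reserve=False)
        b = extract_all(signal, FS, include_reserve=False)
        assert a == b

    def test_invariants(self, signal):
        f = extract_all(signal, FS, include_reserve=False)
        assert f["variance"] >= 0
        assert f["q1"] <= f["q2"] <= f["q3"]
        assert f["iqr"] == pytest.approx(f["q3"] - f["q1"])
        assert f["peak_to_peak"] == pytest.approx(f["max"] - f["min"])
        for name in ("energy_entropy", "shannon_entropy", "sample_entropy",
                     "approximate_entropy", "mspe", "exponential_entropy"):
            assert f[name] >= 0
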