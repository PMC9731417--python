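import numpy as np
import pytest

from pcgfusion import SynthSpec, decompose, generate
from pcgfusion.errors import DegenerateSignalError, SelectionError
from pcgfusion.selection import (adaptive_hd_select, adaptive_hd_threshold,
                                 corr_rmse_select, corr_rmse_thresholds,
                                 correlation, fixed_hd_select, hausdorff,
                                 reconstruct, rmse, signal_to_pointset)


def brute_force_hausdorff(a, b):
    """Direct O(nm) evaluation of max[h(A,B), h(B,A)] under the 2-norm."""
    a = np.atleast_2d(np.asarray(a, float).T).T
    b = np.atleast_2d(np.asarray(b, float).T).T
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestCorrelation:
    def test_self_is_one(self):
        s = np.array([1.0, 5.0, 2.0, 8.0])
        assert correlation(s, s) == pytest.approx(1.0)

    def test_sign_flip_is_minus_one(self):
        s = np.array([1.0, 5.0, 2.0, 8.0])
        assert correlation(s, -s) == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        assert correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_raises(self):
        with pytest.raises(DegenerateSignalError):
            correlation([1, 1, 1], [1, 2, 3])


class TestRmse:
    def test_identity_zero(self):
        s = np.array([1.0, -2.0, 3.0])
        assert rmse(s, s) == 0.0

    def test_hand_computed(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        s, c = rng.standard_normal(50), rng.standard_normal(50)
        assert rmse(s, c) == rmse(c, s)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])


class TestHausdorff:
    def test_self_distance_zero(self):
        pts = np.random.default_rng(1).standard_normal((30, 2))
        assert hausdorff(pts, pts) == 0.0

    def test_one_dimensional_example(self):
        assert hausdorff(np.array([0.0, 1.0]), np.array([0.0, 2.0])) == 1.0

    @pytest.mark.parametrize("dim", [1, 2])
    def test_matches_brute_force_oracle(self, dim):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.standard_normal((int(rng.integers(2, 100)), dim))
            b = rng.standard_normal((int(rng.integers(2, 100)), dim))
            assert hausdorff(a, b) == brute_force_hausdorff(a, b)

    def test_symmetric_nonnegative_triangle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b, c = (rng.standard_normal((20, 2)) for _ in range(3))
            hab, hba = hausdorff(a, b), hausdorff(b, a)
            assert hab == hba >= 0
            assert hausdorff(a, c) <= hab + hausdorff(b, c) + 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.empty((0, 2)), np.ones((3, 2)))


class TestThresholdArithmetic:
    def test_corr_rmse_two_imfs(self):
        lam, delta, selected, fb = corr_rmse_thresholds([0.9, 0.1], [0.2, 0.8])
        assert lam == pytest.approx(0.9)
        assert delta == pytest.approx(0.2)
        assert selected == (1,)
        assert not fb

    def test_corr_rmse_identical_scores_selects_all_candidates(self):
        lam, delta, selected, _ = corr_rmse_thresholds([0.5] * 6, [0.3] * 6)
        assert lam == pytest.approx(0.5) and delta == pytest.approx(0.3)
        assert selected == (1, 2, 3, 4, 5)   # layers 1..L-1, boundary inclusive

    def test_adaptive_hd_worked_example(self):
        eps, selected, fb = adaptive_hd_threshold([5, 1, 1, 1, 1, 5, 5])
        assert eps == pytest.approx(19 / 7)
        assert selected == (2, 3, 4, 5)
        assert not fb

    def test_adaptive_hd_all_equal_selects_all(self):
        eps, selected, _ = adaptive_hd_threshold([2.0] * 7)
        assert eps == pytest.approx(2.0)
        assert selected == tuple(range(1, 8))

    def test_adaptive_hd_short_decomposition_keeps_denominator_seven(self):
        eps, selected, fb = adaptive_hd_threshold([1.0, 2.0, 3.0, 4.0])
        assert eps == pytest.approx(10 / 7)
        assert selected == (1,)

    def test_corr_rmse_needs_two_imfs(self):
        with pytest.raises(SelectionError):
            corr_rmse_thresholds([0.5], [0.5])

    def test_monotonicity_raising_corr_never_drops_a_layer(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            corr = rng.uniform(0, 1, 6)
            errs = rng.uniform(0, 1, 6)
            _, _, sel, _ = corr_rmse_thresholds(corr, errs)
            for i in list(sel):
                boosted = corr.copy()
                boosted[i - 1] = min(1.0, boosted[i - 1] + 0.2)
                _, _, sel2, _ = corr_rmse_thresholds(boosted, errs)
                assert i in sel2


@pytest.fixture(scope="module")
def clean_pcg():
    spec = SynthSpec(snr=np.inf, duration=2.0, seed=11)
    rec, _, _ = generate(spec)
    return rec.samples, decompose(rec.samples)


class TestSelectionOnSignals:
    def test_corr_rmse_report_consistent(self, clean_pcg):
        s, imfs = clean_pcg
        rep = corr_rmse_select(s, imfs)
        assert len(rep.corr) == len(rep.rmse) == len(imfs)
        for i in rep.selected:
            assert rep.corr[i - 1] >= rep.lambda_thr
            assert rep.rmse[i - 1] <= rep.delta_thr

    def test_adaptive_hd_report_consistent(self, clean_pcg):
        s, imfs = clean_pcg
        rep = adaptive_hd_select(s, imfs, 2205.0)
        assert len(rep.hd) == min(7, len(imfs))
        for i in rep.selected:
            assert i <= 7 and rep.hd[i - 1] <= rep.epsilon_thr

    @pytest.mark.parametrize("select_fn", [corr_rmse_select,
                                           lambda s, i: adaptive_hd_select(s, i, 2205.0),
                                           lambda s, i: fixed_hd_select(s, i, 2205.0)])
    def test_selected_layers_carry_most_energy(self, clean_pcg, select_fn):
        s, imfs = clean_pcg
        rep = select_fn(s, imfs)
        energies = np.array([np.sum(c ** 2) for c in imfs.imfs])
        kept = sum(energies[i - 1] for i in rep.selected)
        assert kept / energies.sum() >= 0.9

    def test_highest_correlation_layer_always_selected(self):
        fs = 2205
        t = np.arange(int(1.5 * fs)) / fs
        tone = np.sin(2 * np.pi * 40 * t)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = tone + 0.2 * rng.standard_normal(t.size)
            imfs = decompose(x)
            rep = corr_rmse_select(x, imfs)
            best = int(np.argmax([abs(np.corrcoef(tone, c)[0, 1])
                                  for c in imfs.imfs])) + 1
            assert best in rep.selected

    def test_selection_report_roundtrips_to_json(self, clean_pcg, tmp_path):
        import json
        s, imfs = clean_pcg
        rep = adaptive_hd_select(s, imfs, 2205.0)
        path = tmp_path / "report.json"
        rep.to_json(path)
        data = json.loads(path.read_text())
        assert tuple(data["selected"]) == rep.selected
        assert data["epsilon_thr"] == pytest.approx(rep.epsilon_thr)


class TestReconstruct:
    def test_all_layers_plus_residue_restores_signal(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1500).cumsum()
        imfs = decompose(x)
        y = reconstruct(imfs, range(1, len(imfs) + 1), include_residue=True)
        assert np.linalg.norm(x - y) / np.linalg.norm(x) < 1e-8

    def test_singleton_selection_is_that_layer(self):
        x = np.random.default_rng(4).standard_normal(1200)
        imfs = decompose(x)
        np.testing.assert_array_equal(reconstruct(imfs, [1]), imfs.imfs[0])

    def test_empty_selection_rejected(self):
        x = np.random.default_rng(4).standard_normal(1200)
        with pytest.raises(SelectionError):
            reconstruct(decompose(x), [])

    def test_spectrum_embedding_denoises_noisy_tone(self):
        """With the spectrum point-set option the adaptive-HD rule acts as a
        denoiser: >= 3 dB median SNR gain on a tone buried at 0 dB."""
        fs = 2205
        t = np.arange(2 * fs) / fs
        tone = np.sin(2 * np.pi * 30 * t)

        def snr_db(sig):
            return 10 * np.log10(np.sum(tone ** 2) / np.sum((sig - tone) ** 2))

        gains = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = tone + rng.standard_normal(t.size) * np.sqrt(np.mean(tone ** 2))
            imfs = decompose(x)
            rep = adaptive_hd_select(x, imfs, fs, hd_space="spectrum")
            gains.append(snr_db(reconstruct(imfs, rep.selected)) - snr_db(x))
        assert np.median(gains) >= 3.0


class TestPointsetEmbedding:
    def test_time_amplitude_shape_and_scale(self):
        x = np.array([0.0, 2.0, -4.0, 1.0] * 100)
        pts = signal_to_pointset(x, fs=100.0)
        assert pts.shape == (400, 2)
        assert np.max(np.abs(pts[:, 1])) == pytest.approx(1.0)

    def test_decimation_bounds_point_count(self):
        x = np.random.default_rng(0).standard_normal(10000)
        pts = signal_to_pointset(x, fs=2205.0, hd_max_points=2000)
        assert pts.shape[0] <= 2000

    def test_amplitude_1d_option(self):
        x = np.array([1.0, -2.0, 3.0])
        pts = signal_to_pointset(x, fs=10.0, hd_space="amplitude_1d")
        assert pts.shape == (3, 1)
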