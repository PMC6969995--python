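"""EMG descriptors: spectral, scalogram and convex-hull operations."""
import numpy as np
import pytest

import fatiguekit as fk
from fatiguekit import emg
from fatiguekit.exceptions import (DegenerateInputError, InvalidInputError,
                                   UndefinedResultError)


class TestRms:
    def test_values(self):
        assert emg.rms(np.zeros(10)) == 0.0
        assert emg.rms(np.full(7, -2.5)) == pytest.approx(2.5)
        assert emg.rms(np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            emg.rms(np.array([]))


class TestPowerSpectrum:
    def test_tone_peaks_at_its_frequency(self):
        fs = 1000.0
        x = np.sin(2 * np.pi * 100 * np.arange(1024) / fs)
        spec = emg.power_spectrum(x, fs)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(100, abs=1.0)

    def test_parseval_on_white_noise(self, rng):
        fs = 1000.0
        x = rng.normal(size=4096)
        spec = emg.power_spectrum(x, fs)
        # periodogram density integrates to the variance of the detrended signal
        power = np.trapezoid(spec.power, spec.freqs)
        assert power == pytest.approx(np.var(x), rel=0.01)

    def test_zero_signal(self):
        spec = emg.power_spectrum(np.zeros(64), 1000.0)
        assert np.allclose(spec.power, 0.0)

    def test_short_segment_raises(self):
        with pytest.raises(InvalidInputError):
            emg.power_spectrum(np.zeros(4), 1000.0)


class TestMedianFrequency:
    def test_flat_spectrum_halves_the_band(self):
        f = np.linspace(0, 500, 501)
        mf = emg.median_frequency(emg.Spectrum(f, np.ones_like(f)))
        assert mf == pytest.approx(250, abs=1.0)

    def test_single_line(self):
        f = np.linspace(0, 500, 501)
        p = np.zeros_like(f)
        p[123] = 4.2
        assert emg.median_frequency(emg.Spectrum(f, p)) == pytest.approx(f[123])

    def test_two_equal_lines_interpolate_between(self):
        f = np.linspace(0, 200, 201)
        p = np.zeros_like(f)
        p[50] = p[150] = 1.0
        # an exact even split resolves to the plateau midpoint
        assert emg.median_frequency(emg.Spectrum(f, p)) == pytest.approx(100.0)

    def test_zero_power_raises(self):
        f = np.linspace(0, 10, 11)
        with pytest.raises(UndefinedResultError):
            emg.median_frequency(emg.Spectrum(f, np.zeros_like(f)))

    def test_decreases_when_mass_shifts_down(self, rng):
        f = np.linspace(0, 500, 251)
        p = rng.uniform(0.1, 1.0, size=f.size)
        shifted = p * np.linspace(2.0, 0.5, f.size)  # boost low, damp high
        assert (emg.median_frequency(emg.Spectrum(f, shifted))
                < emg.median_frequency(emg.Spectrum(f, p)))


def test_total_power_cases(rng):
    f = np.linspace(0, 100, 51)
    assert emg.total_power(emg.Spectrum(f, np.zeros_like(f))) == 0.0
    p = np.zeros_like(f)
    p[7] = 3.25
    assert emg.total_power(emg.Spectrum(f, p)) == pytest.approx(3.25)


class TestMorletScales:
    @pytest.mark.parametrize("freq,scale", [
        (5.0, 162.5), (7.0, 116.071), (9.0, 90.278), (499.0, 1.628),
    ])
    def test_reference_scale_array_endpoints(self, freq, scale):
        cfg = emg.ScalogramConfig(fs=1000.0, pseudofreqs=np.array([freq]))
        assert emg.morlet_scales(cfg)[0] == pytest.approx(scale, abs=5e-4)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(InvalidInputError):
            emg.ScalogramConfig(fs=1000.0, pseudofreqs=np.array([-5.0]))


class TestScalogram:
    def test_tone_localizes_at_nearest_row(self):
        fs = 1000.0
        x = np.sin(2 * np.pi * 100 * np.arange(1000) / fs)
        S = emg.compute_scalogram(x, emg.ScalogramConfig(fs=fs))
        best = S.freq_axis[np.argmax(S.S.mean(axis=1))]
        assert abs(best - 100) <= 2.0

    def test_zero_signal_gives_zero_scalogram(self):
        S = emg.compute_scalogram(np.zeros(200), emg.ScalogramConfig())
        assert np.allclose(S.S, 0.0)

    def test_chirp_ridge_descends(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = np.cos(2 * np.pi * (150 * t - 25 * t ** 2))  # 150 -> 50 Hz
        S = emg.compute_scalogram(x, emg.ScalogramConfig(fs=fs))
        ridge = S.freq_axis[np.argmax(S.S, axis=0)]
        # smooth the per-column argmax and drop edges (cone of influence)
        k = 100
        sm = np.convolve(ridge, np.ones(k) / k, mode="valid")[200:-200]
        assert np.polyfit(np.arange(sm.size), sm, 1)[0] < 0


class TestCentroid:
    def test_point_mass(self):
        S = emg.Scalogram(np.zeros((5, 7)), np.arange(7) * 0.1, np.arange(5) * 2.0)
        S.S[3, 4] = 9.0
        mt, mf = emg.scalogram_centroid(S, "intensity")
        assert (mt, mf) == (pytest.approx(0.4), pytest.approx(6.0))

    def test_uniform_gives_axis_means(self):
        ta, fa = np.arange(8) * 0.5, np.arange(4) * 3.0
        S = emg.Scalogram(np.ones((4, 8)), ta, fa)
        mt, mf = emg.scalogram_centroid(S, "intensity")
        assert mt == pytest.approx(ta.mean())
        assert mf == pytest.approx(fa.mean())

    def test_literal_mode_matches_double_loop(self, rng):
        M = rng.uniform(size=(4, 5))
        ta, fa = np.arange(5) * 0.2, np.arange(4) * 1.5
        S = emg.Scalogram(M, ta, fa)
        num_t = sum(ta[j] * M[i, j] for i in range(4) for j in range(5))
        num_f = sum(fa[i] * M[i, j] for i in range(4) for j in range(5))
        mt, mf = emg.scalogram_centroid(S, "literal")
        assert mt == pytest.approx(num_t / 20)
        assert mf == pytest.approx(num_f / 20)

    def test_intensity_mode_scale_invariant_literal_scales(self, rng):
        M = rng.uniform(0.1, 1.0, size=(6, 9))
        S1 = emg.Scalogram(M, np.arange(9.0), np.arange(6.0))
        S2 = emg.Scalogram(3.5 * M, np.arange(9.0), np.arange(6.0))
        assert emg.scalogram_centroid(S1) == pytest.approx(emg.scalogram_centroid(S2))
        l1 = emg.scalogram_centroid(S1, "literal")
        l2 = emg.scalogram_centroid(S2, "literal")
        assert l2 == pytest.approx(tuple(3.5 * np.array(l1)))

    def test_zero_scalogram_raises_in_intensity_mode(self):
        S = emg.Scalogram(np.zeros((3, 3)), np.arange(3.0), np.arange(3.0))
        with pytest.raises(UndefinedResultError):
            emg.scalogram_centroid(S, "intensity")


def test_mean_power(rng):
    M = rng.uniform(size=(5, 6))
    S = emg.Scalogram(M, np.arange(6.0), np.arange(5.0))
    assert emg.mean_power(S) == pytest.approx(M.mean())
    S0 = emg.Scalogram(np.full((2, 2), 3.3), np.arange(2.0), np.arange(2.0))
    assert emg.mean_power(S0) == pytest.approx(3.3)


def otsu_oracle(values, levels=256):
    """Exhaustive between-class-variance maximization on the quantized
    histogram."""
    lo, hi = values.min(), values.max()
    q = np.round((values - lo) / (hi - lo) * (levels - 1)).astype(int)
    best_t, best_var = 0, -1.0
    for t in range(levels - 1):
        m0 = q <= t
        m1 = ~m0
        if not m0.any() or not m1.any():
            continue
        w0, w1 = m0.mean(), m1.mean()
        var = w0 * w1 * (q[m0].mean() - q[m1].mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return lo + (best_t + 1) / (levels - 1) * (hi - lo)  # mask = above class


class TestOtsu:
    def test_bimodal_blocks_separated(self):
        M = np.full((10, 10), 0.1)
        M[:5] = 0.9
        S = emg.Scalogram(M, np.arange(10.0), np.arange(10.0))
        mask = emg.otsu_mask(S)
        assert mask[:5].all() and not mask[5:].any()

    def test_binary_values_separate(self):
        M = np.zeros((4, 4))
        M[0, 0] = 1.0
        S = emg.Scalogram(M, np.arange(4.0), np.arange(4.0))
        mask = emg.otsu_mask(S)
        assert mask.sum() == 1 and mask[0, 0]

    def test_threshold_matches_exhaustive_search(self, rng):
        for _ in range(5):
            M = np.concatenate([rng.normal(0.2, 0.05, 60),
                                rng.normal(0.8, 0.05, 40)]).reshape(10, 10)
            M = np.clip(M, 0, 1)
            S = emg.Scalogram(M, np.arange(10.0), np.arange(10.0))
            mask = emg.otsu_mask(S)
            oracle_thr = otsu_oracle(M.ravel())
            assert np.array_equal(mask, M >= oracle_thr) or \
                abs(mask.sum() - (M >= oracle_thr).sum()) <= 2

    def test_constant_scalogram_raises(self):
        S = emg.Scalogram(np.ones((3, 3)), np.arange(3.0), np.arange(3.0))
        with pytest.raises(DegenerateInputError):
            emg.otsu_mask(S)


class TestConvexDescriptors:
    def test_rectangle_geometry(self):
        dt, df = 0.01, 2.0
        M = np.zeros((20, 30))
        M[5:10, 10:16] = 1.0  # 5 rows x 6 cols of pixels
        S = emg.Scalogram(M, np.arange(30) * dt, np.arange(20) * df)
        d = emg.convex_descriptors(S, M > 0)
        assert d.time_dispersion == pytest.approx(5 * dt)   # 6 pixels span 5 steps
        assert d.frequency_dispersion == pytest.approx(4 * df)
        assert d.area == pytest.approx(5 * dt * 4 * df)
        assert d.volume == pytest.approx(30.0)

    def test_single_pixel(self):
        M = np.zeros((5, 5))
        M[2, 2] = 7.0
        S = emg.Scalogram(M, np.arange(5.0), np.arange(5.0))
        d = emg.convex_descriptors(S, M > 0)
        assert d.time_dispersion == 0 and d.frequency_dispersion == 0
        assert d.volume == pytest.approx(7.0)
        assert d.area == 0

    def test_hull_volume_dominates_masked_sum(self, rng):
        M = rng.uniform(size=(15, 15))
        mask = rng.uniform(size=(15, 15)) > 0.7
        if mask.sum() < 3:
            mask[0, 0] = mask[3, 7] = mask[10, 2] = True
        S = emg.Scalogram(M, np.arange(15.0), np.arange(15.0))
        d = emg.convex_descriptors(S, mask)
        assert d.volume >= M[mask].sum() - 1e-9


def test_wavelet_median_frequency_on_tone():
    fs = 1000.0
    x = np.sin(2 * np.pi * 80 * np.arange(1000) / fs)
    S = emg.compute_scalogram(x, emg.ScalogramConfig(fs=fs))
    assert emg.wavelet_median_frequency(S) == pytest.approx(80, abs=15)


def test_activation_descriptor_table_has_all_parameters():
    rng = np.random.default_rng(0)
    x = rng.normal(size=800)
    d = emg.activation_descriptors(x, 1000.0)
    assert set(d) == set(emg.EMG_PARAM_IDS)
    assert all(np.isfinite(v) for v in d.values())
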