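import numpy as np
import pytest

from ecogflex import (MorletParams, PreprocessConfig, RawRecording, Spectrogram,
                      alt_wavelet_spectrogram, bandpass_filter, downsample_time,
                      interpolate_fingers, morlet_spectrogram, morlet_wavelet,
                      normalize_channels, notch_filter, preprocess_recording)

FS = 1000.0


def tone(f, dur=10.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * f * t)[None, :]


def fft_amp(x, f, fs=FS):
    """Amplitude of the FFT bin nearest frequency f."""
    spec = np.abs(np.fft.rfft(x.ravel()))
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[np.argmin(np.abs(freqs - f))]


class TestInterpolateFingers:
    def test_constant_preserved(self):
        out = interpolate_fingers(np.full((5, 25), 0.7))
        assert out.shape == (5, 100)
        np.testing.assert_allclose(out, 0.7, atol=1e-12)

    def test_passes_through_knots(self, rng):
        fingers = rng.random((5, 50))
        out = interpolate_fingers(fingers)
        np.testing.assert_allclose(out[:, ::4], fingers, atol=1e-9)

    def test_reproduces_cubic_polynomial(self):
        # cubic splines are exact on cubics; oracle = direct evaluation
        t25 = np.arange(30) / 25.0
        poly = lambda t: 0.3 * t**3 - 0.8 * t**2 + 0.1 * t + 2.0
        out = interpolate_fingers(np.tile(poly(t25), (5, 1)))
        t100 = np.arange(120) / 100.0
        inside = t100 <= t25[-1]  # spline is exact between knots
        np.testing.assert_allclose(out[0, inside], poly(t100[inside]), atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 4"):
            interpolate_fingers(np.zeros((5, 3)))


class TestNormalizeChannels:
    def test_matches_two_step_definition(self, rng):
        x = rng.normal(3.0, 2.5, size=(4, 1001))
        out = normalize_channels(x)
        for c in range(4):  # brute-force recomputation per channel
            z = (x[c] - x[c].mean()) / x[c].std()
            np.testing.assert_allclose(out[c], z - np.median(z), atol=1e-12)
        np.testing.assert_allclose(np.median(out, axis=1), 0.0, atol=1e-15)
        assert np.allclose(out.std(axis=1), 1.0, atol=0.01)

    def test_symmetric_input_median_step_noop(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        out = normalize_channels(x)
        z = (x - 3.0) / x.std()
        np.testing.assert_allclose(out, z, atol=1e-12)

    def test_zero_variance_names_channel(self):
        x = np.vstack([np.random.default_rng(0).normal(size=100), np.full(100, 2.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_channels(x)


class TestFilters:
    @pytest.mark.parametrize("f,min_db,max_db", [(100, -3, 3), (200, -3, 3)])
    def test_bandpass_passband(self, f, min_db, max_db):
        out = bandpass_filter(tone(f), FS)
        db = 20 * np.log10(fft_amp(out, f) / fft_amp(tone(f), f))
        assert min_db <= db <= max_db

    @pytest.mark.parametrize("f", [5, 10, 400])
    def test_bandpass_stopband(self, f):
        out = bandpass_filter(tone(f), FS)
        db = 20 * np.log10(fft_amp(out, f) / fft_amp(tone(f), f))
        assert db <= -20

    def test_bandpass_zero_and_design_error(self):
        np.testing.assert_allclose(bandpass_filter(np.zeros((2, 5000)), FS), 0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(tone(100), 500.0, 40, 300)

    @pytest.mark.parametrize("f", [60, 120, 180])
    def test_notch_attenuates_line_and_harmonics(self, f):
        out = notch_filter(tone(f), FS)
        db = 20 * np.log10(fft_amp(out, f) / fft_amp(tone(f), f))
        assert db <= -20

    @pytest.mark.parametrize("f", [50, 90, 100, 250])
    def test_notch_leaves_neighbors(self, f):
        out = notch_filter(tone(f), FS)
        db = 20 * np.log10(fft_amp(out, f) / fft_amp(tone(f), f))
        assert abs(db) <= 3

    def test_notch_skips_super_nyquist_harmonic(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ecogflex"):
            notch_filter(tone(90, dur=2.0), FS, harmonics=[120.0, 600.0])
        assert any("skipped" in r.message for r in caplog.records)


class TestMorlet:
    def test_sigma_formula(self):
        p = MorletParams(n_cycles=7)
        np.testing.assert_allclose(p.sigma(100.0), 7 / (2 * np.pi * 100), rtol=1e-12)
        # sigma strictly decreasing in f
        s = p.sigma(p.freqs)
        assert np.all(np.diff(s) < 0)

    def test_grid_pins_endpoints(self):
        p = MorletParams(n_freqs=17)
        assert p.freqs[0] == 40.0 and p.freqs[-1] == pytest.approx(300.0)
        assert np.all(np.diff(p.freqs) > 0)

    @pytest.mark.parametrize("f0", [47.0, 100.0, 161.0, 280.0])
    def test_tone_peaks_at_nearest_grid_bin(self, f0, small_morlet):
        spec = morlet_spectrogram(tone(f0, dur=4.0), FS, small_morlet)
        profile = spec.values[0].mean(axis=1)
        assert np.argmax(profile) == np.argmin(np.abs(small_morlet.freqs - f0))

    def test_analytic_gaussian_response(self):
        # response of the unit-L2 Morlet bank to a tone at a grid frequency:
        # amp(f) ∝ sqrt(sigma(f)) * exp(-(2 pi sigma(f))^2 (f - f0)^2 / 2)
        p = MorletParams(n_freqs=24)
        j0 = 12
        f0 = p.freqs[j0]
        spec = morlet_spectrogram(tone(f0, dur=8.0), FS, p)
        mid = spec.values[0, :, 2000:-2000].mean(axis=1)  # avoid edge taper
        sig = p.sigma(p.freqs)
        analytic = np.sqrt(sig) * np.exp(-0.5 * (2 * np.pi * sig) ** 2 * (p.freqs - f0) ** 2)
        for j in (j0 - 1, j0 + 1):
            assert mid[j] / mid[j0] == pytest.approx(analytic[j] / analytic[j0], rel=0.05)

    def test_zero_signal_and_linearity(self, small_morlet, rng):
        z = morlet_spectrogram(np.zeros((2, 3000)), FS, small_morlet)
        np.testing.assert_array_equal(z.values, 0.0)
        x = rng.normal(size=(1, 3000))
        s1 = morlet_spectrogram(x, FS, small_morlet).values
        s3 = morlet_spectrogram(3.0 * x, FS, small_morlet).values
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-4, atol=1e-6)

    def test_support_longer_than_signal(self):
        with pytest.raises(ValueError, match="n_cycles"):
            morlet_spectrogram(np.zeros((1, 200)), FS, MorletParams(n_freqs=3))

    def test_matches_mne_oracle(self, rng):
        """Independent implementation check against MNE's Morlet TFR."""
        mne = pytest.importorskip("mne")
        x = rng.normal(size=(1, 4000))
        p = MorletParams(n_freqs=6)
        mine = morlet_spectrogram(x, FS, p).values[0]
        theirs = mne.time_frequency.tfr_array_morlet(
            x[None, :, :], FS, p.freqs, n_cycles=7.0, output="complex", verbose=False
        )[0, 0]
        for j in range(6):  # same shape up to normalization convention
            a, b = mine[j, 500:-500], np.abs(theirs[j, 500:-500])
            assert np.corrcoef(a, b)[0, 1] > 0.999

    def test_unit_l2_norm(self):
        psi = morlet_wavelet(100.0, 7 / (2 * np.pi * 100), FS)
        assert np.linalg.norm(psi) == pytest.approx(1.0)


class TestDownsample:
    def test_constant_and_length(self):
        spec = Spectrogram(np.full((2, 3, 1000), 5.0), FS, np.arange(3) + 1.0)
        out = downsample_time(spec, 100.0)
        assert out.values.shape == (2, 3, 100) and out.fs == 100.0
        np.testing.assert_allclose(out.values, 5.0)

    def test_block_mean_oracle(self, rng):
        v = rng.random((1, 2, 47)).astype(np.float32)
        out = downsample_time(Spectrogram(v, 10.0, np.array([1.0, 2.0])), 2.0)
        assert out.values.shape[-1] == 9  # floor(47/5)
        for b in range(9):  # brute-force mean over each block
            np.testing.assert_allclose(out.values[..., b], v[..., 5 * b : 5 * b + 5].mean(-1),
                                       rtol=1e-6)

    def test_non_integer_factor(self):
        spec = Spectrogram(np.zeros((1, 1, 30)), 1000.0, np.array([50.0]))
        with pytest.raises(ValueError, match="integer multiple"):
            downsample_time(spec, 300.0)


@pytest.fixture(scope="module")
def am_recording():
    """An 80 Hz carrier modulated by a known envelope, low noise."""
    rng = np.random.default_rng(5)
    dur, fs = 20.0, 1000.0
    t = np.arange(int(dur * fs)) / fs
    env = 0.5 * (1 - np.cos(2 * np.pi * 0.5 * t))  # 0.5 Hz raised cosine
    x = env * np.sin(2 * np.pi * 80.0 * t) + 0.05 * rng.normal(size=t.size)
    fingers = np.tile(env[:: int(fs / 25)], (5, 1))
    return RawRecording(ecog=np.tile(x, (2, 1)), fingers=fingers), env


class TestPreprocessRecording:
    def test_known_envelope_tracked(self, am_recording):
        rec, env = am_recording
        cfg = PreprocessConfig(morlet=MorletParams(n_freqs=16))
        spec, fingers = preprocess_recording(rec, cfg)
        j = np.argmin(np.abs(spec.freqs - 80.0))
        energy = spec.values[0, j]
        env100 = env[::10][: energy.size]
        r = np.corrcoef(energy, env100)[0, 1]
        assert r > 0.8

    def test_time_axes_aligned(self, am_recording):
        rec, _ = am_recording
        spec, fingers = preprocess_recording(rec, PreprocessConfig(morlet=MorletParams(n_freqs=8)))
        assert spec.n_times == fingers.shape[1]
        assert spec.fs == 100.0

    def test_frame_count_matches_duration(self, small_recording):
        cfg = PreprocessConfig(morlet=MorletParams(n_freqs=8))
        spec, fingers = preprocess_recording(small_recording, cfg)
        expected = int(small_recording.duration * 100)
        assert abs(spec.n_times - expected) <= 1


class TestAltWavelets:
    @pytest.mark.parametrize("family", ["haar", "daubechies", "symlet"])
    def test_shape_contract_and_zero(self, family, small_morlet):
        z = alt_wavelet_spectrogram(np.zeros((2, 2000)), FS, family, small_morlet)
        assert z.values.shape == (2, small_morlet.n_freqs, 2000)
        np.testing.assert_allclose(z.values, 0.0, atol=1e-12)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unsupported"):
            alt_wavelet_spectrogram(np.zeros((1, 1000)), FS, "meyer")
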