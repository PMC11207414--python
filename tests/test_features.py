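import numpy as np
import pytest

from heartframe import features as ft
from heartframe.synthetic import SynthParams, synth_heart_sound

FS = 2000


class TestSignalEntropy:
    def test_constant_frame_zero_bits(self):
        assert ft.signal_entropy(np.full(1000, 0.3)) == 0.0

    def test_uniform_bins_log2(self):
        # 64 samples, one per histogram bin center -> log2(64) bits
        centers = -1 + (np.arange(64) + 0.5) * (2 / 64)
        assert ft.signal_entropy(centers) == pytest.approx(6.0)

    def test_matches_brute_force_histogram(self):
        from collections import Counter

        rng = np.random.default_rng(17)
        x = np.clip(rng.normal(0, 0.3, 5000), -1, 1)
        bins = np.linspace(-1, 1, 65)
        idx = np.clip(np.searchsorted(bins, x, side="right") - 1, 0, 63)
        counts = Counter(idx.tolist())
        expected = -sum((c / 5000) * np.log2(c / 5000) for c in counts.values())
        assert ft.signal_entropy(x) == pytest.approx(expected, rel=1e-9)


class TestEnvelope:
    def test_tracks_amplitude_modulation(self):
        t = np.arange(5 * FS) / FS
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
        x = modulator * np.sin(2 * np.pi * 150 * t)
        env = ft.homomorphic_envelope(x)
        core = slice(FS // 2, -FS // 2)
        rms_err = np.sqrt(np.mean((env[core] - modulator[core]) ** 2))
        assert rms_err / np.sqrt(np.mean(modulator[core] ** 2)) < 0.05

    def test_constant_tone_near_constant(self, tone):
        env = ft.homomorphic_envelope(tone.samples)
        core = env[FS // 2 : -FS // 2]
        assert np.std(core) / np.mean(core) < 0.02

    def test_strictly_positive(self, frame_5s):
        assert np.all(ft.homomorphic_envelope(frame_5s) > 0)


class TestCycleAndSystole:
    @pytest.mark.parametrize("hr,sf", [(60.0, 0.35), (75.0, 0.35), (100.0, 0.32)])
    def test_ground_truth_recovery(self, hr, sf):
        sig, truth = synth_heart_sound(
            SynthParams(duration=10.0, heart_rate=hr, systole_fraction=sf, seed=int(hr))
        )
        est_hr, est_sys = ft.cycle_and_systole(sig.samples[: 5 * FS])
        assert est_hr == pytest.approx(hr, abs=3.0)
        assert est_sys == pytest.approx(truth.systolic_interval, abs=0.03)

    def test_rate_bounded_by_lag_window(self):
        rng = np.random.default_rng(23)
        hr, _ = ft.cycle_and_systole(rng.standard_normal(5 * FS))
        assert 30.0 <= hr <= 120.0


class TestSpectralFeatures:
    def test_pure_tone_integer_periods(self):
        t = np.arange(2 * FS) / FS
        out = ft.spectral_features(np.sin(2 * np.pi * 100 * t))
        assert out["dominant_freq"] == pytest.approx(100.0)
        assert out["max_spectrum_ratio"] > 0.99
        assert out["norm_spectral_entropy"] < 0.05

    def test_white_noise_entropy_near_one(self):
        x = np.random.default_rng(29).standard_normal(5 * FS)
        out = ft.spectral_features(x)
        assert out["norm_spectral_entropy"] == pytest.approx(1.0, abs=0.05)

    def test_parseval_consistency(self, frame_5s):
        power = np.abs(np.fft.rfft(frame_5s)) ** 2
        n = len(frame_5s)
        # one-sided power with double-counted interior bins = N * time energy
        two_sided = 2 * power.sum() - power[0] - (power[n // 2] if n % 2 == 0 else 0)
        assert two_sided == pytest.approx(n * np.sum(frame_5s**2), rel=1e-9)
        out = ft.spectral_features(frame_5s)
        assert out["max_power"] == pytest.approx(power.max())

    def test_all_zero_frame_flagged_zeros(self):
        out = ft.spectral_features(np.zeros(1000))
        assert out == {
            "max_power": 0.0,
            "dominant_freq": 0.0,
            "max_spectrum_ratio": 0.0,
            "norm_spectral_entropy": 0.0,
        }


class TestStatisticalFeatures:
    def test_hand_case(self):
        out = ft.statistical_features([1, 2, 3, 4, 5])
        assert out["mean"] == 3
        assert out["median"] == 3
        assert out["sd"] == pytest.approx(np.sqrt(2.5))
        assert out["mad"] == pytest.approx(1.2)
        assert out["iqr"] == pytest.approx(out["q3"] - out["q1"])
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_frame_zero_skewness(self):
        x = np.concatenate([np.linspace(-1, 1, 50), -np.linspace(-1, 1, 50)])
        assert ft.statistical_features(x)["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(31).standard_normal(100_000)
        assert abs(ft.statistical_features(x)["kurtosis"]) < 0.1

    def test_adjusted_formulas_match_direct_computation(self):
        x = np.random.default_rng(37).exponential(size=200)
        n = len(x)
        s = np.std(x, ddof=1)
        z = (x - x.mean()) / s
        skew_direct = n / ((n - 1) * (n - 2)) * np.sum(z**3)
        kurt_direct = (
            n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * np.sum(z**4)
            - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
        )
        out = ft.statistical_features(x)
        assert out["skewness"] == pytest.approx(skew_direct, rel=1e-9)
        assert out["kurtosis"] == pytest.approx(kurt_direct, rel=1e-9)

    def test_constant_frame_flagged_zero_moments(self):
        out = ft.statistical_features(np.full(10, 2.0))
        assert out["skewness"] == 0.0 and out["kurtosis"] == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ft.statistical_features([1.0, 2.0, 3.0])


class TestWaveletEntropies:
    def test_band_entropy_degenerate_and_uniform(self):
        assert ft._band_entropy(np.array([0.0, 3.0, 0.0])) == 0.0
        assert ft._band_entropy(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(2.0)
        assert ft._band_entropy(np.zeros(8)) == 0.0

    def test_matches_chained_single_level_transform(self):
        import pywt

        x = np.random.default_rng(41).standard_normal(4000)
        approx = x
        details = []
        for _ in range(4):
            approx, d = pywt.dwt(approx, "db5", mode="symmetric")
            details.append(d)

        def entropy(c):
            e = c**2
            p = e[e > 0] / e.sum()
            return -np.sum(p * np.log2(p))

        out = ft.wavelet_entropies(x)
        assert out["wentropy_a4"] == pytest.approx(entropy(approx), rel=1e-9)
        assert out["wentropy_d4"] == pytest.approx(entropy(details[3]), rel=1e-9)
        assert out["wentropy_d3"] == pytest.approx(entropy(details[2]), rel=1e-9)
        assert out["wentropy_d2"] == pytest.approx(entropy(details[1]), rel=1e-9)

    def test_all_entropies_nonnegative(self, frame_5s):
        assert all(v >= 0 for v in ft.wavelet_entropies(frame_5s).values())


def brute_force_mfcc(frame, fs):
    """Independent per-window MFCC: explicit DFT sums and DCT-II cosines."""
    win = int(round(0.025 * fs))
    hop = int(round(0.010 * fs))
    nfft = int(2 ** np.ceil(np.log2(win)))
    n_bins = nfft // 2 + 1
    hamming = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(win) / (win - 1))
    # triangular filters on the 1127*ln(1+f/700) scale
    mel = lambda f: 1127.0 * np.log(1 + f / 700.0)
    imel = lambda m: 700.0 * (np.exp(m / 1127.0) - 1)
    pts = imel(np.linspace(mel(0), mel(fs / 2), 28))
    bin_f = np.arange(n_bins) * fs / nfft
    all_coefs = []
    for s in range(0, len(frame) - win + 1, hop):
        seg = frame[s : s + win] * hamming
        power = np.zeros(n_bins)
        for k in range(n_bins):
            re = np.sum(seg * np.cos(-2 * np.pi * k * np.arange(win) / nfft))
            im = np.sum(seg * np.sin(-2 * np.pi * k * np.arange(win) / nfft))
            power[k] = re**2 + im**2
        log_e = np.empty(26)
        for i in range(26):
            left, center, right = pts[i], pts[i + 1], pts[i + 2]
            w = np.minimum((bin_f - left) / (center - left), (right - bin_f) / (right - center))
            log_e[i] = np.log(max(np.sum(np.clip(w, 0, None) * power), 1e-10))
        coefs = np.empty(13)
        for k in range(13):
            scale = np.sqrt((1 if k == 0 else 2) / 26)
            coefs[k] = scale * np.sum(log_e * np.cos(np.pi * k * (2 * np.arange(26) + 1) / 52))
        all_coefs.append(coefs)
    return np.mean(all_coefs, axis=0)


class TestMFCC:
    def test_mel_scale_closed_form(self):
        assert ft.mel_scale(700.0) == pytest.approx(1127.0 * np.log(2), rel=1e-12)
        assert ft.mel_scale(0.0) == 0.0

    def test_zero_frame_finite_and_deterministic(self):
        a = ft.mfcc_features(np.zeros(FS))
        b = ft.mfcc_features(np.zeros(FS))
        assert a == b
        assert all(np.isfinite(v) for v in a.values())

    def test_matches_brute_force_oracle(self):
        t = np.arange(FS) / FS  # 1 s of 60 Hz tone keeps the oracle fast
        frame = 0.5 * np.sin(2 * np.pi * 60 * t)
        expected = brute_force_mfcc(frame, FS)
        out = ft.mfcc_features(frame)
        got = np.array([out[f"mfcc_{i}"] for i in range(1, 14)])
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_frame_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            ft.mfcc_features(np.zeros(10))


class TestExtract:
    def test_vector_has_33_named_features(self, frame_5s):
        out = ft.extract_features(frame_5s)
        assert list(out) == ft.FEATURE_NAMES
        assert len(out) == 33
        assert all(np.isfinite(v) for v in out.values())

    def test_domain_counts(self):
        assert (
            len(ft.TIME_FEATURES),
            len(ft.FREQ_FEATURES),
            len(ft.STAT_FEATURES),
            len(ft.WAVELET_FEATURES),
            len(ft.MFCC_FEATURES),
        ) == (3, 4, 9, 4, 13)

    def test_deterministic(self, frame_5s):
        assert ft.extract_features(frame_5s) == ft.extract_features(frame_5s.copy())

    def test_invariants_on_synthetic_frame(self, frame_5s):
        out = ft.extract_features(frame_5s)
        assert 0 < out["max_spectrum_ratio"] <= 1
        assert 0 <= out["norm_spectral_entropy"] <= 1
        assert out["iqr"] == pytest.approx(out["q3"] - out["q1"])
        assert out["signal_entropy"] >= 0
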