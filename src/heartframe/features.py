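"""Frame-level scalar features for unsegmented heart sounds.

33 features per 5 s frame, in five groups:

* time (3): amplitude-histogram Shannon entropy, heart rate and systolic
  interval estimated from the autocorrelation of the homomorphic
  envelope (no S1/S2 segmentation anywhere);
* frequency (4): maximum of the one-sided power spectrum, its frequency,
  the max-to-total power ratio, and normalized spectral entropy;
* statistical (9): mean, median, sample SD, mean absolute deviation,
  quartiles, IQR, adjusted skewness and excess kurtosis;
* wavelet (4): Shannon entropy of the normalized coefficient energies in
  the A4, D4, D3 and D2 bands of a 4-level db5 decomposition;
* cepstral (13): mean MFCCs c0..c12 over 25 ms Hamming windows.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.fft import dct, rfft, rfftfreq
from scipy.signal import butter, filtfilt, find_peaks, hilbert
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .io import WORKING_FS

TIME_FEATURES = ["signal_entropy", "heart_rate", "systolic_interval"]
FREQ_FEATURES = ["max_power", "dominant_freq", "max_spectrum_ratio", "norm_spectral_entropy"]
STAT_FEATURES = ["mean", "median", "sd", "mad", "q1", "q3", "iqr", "skewness", "kurtosis"]
WAVELET_FEATURES = ["wentropy_a4", "wentropy_d4", "wentropy_d3", "wentropy_d2"]
MFCC_FEATURES = [f"mfcc_{i}" for i in range(1, 14)]

FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES + STAT_FEATURES + WAVELET_FEATURES + MFCC_FEATURES
N_FEATURES = len(FEATURE_NAMES)  # 33

ENTROPY_BINS = 64
CYCLE_LAG_WINDOW = (0.5, 2.0)  # s; heart rate confined to [30, 120] bpm
SYSTOLE_MIN_LAG = 0.2  # s
ENVELOPE_LP_HZ = 8.0
EPS = 1e-10

MFCC_WINDOW_S = 0.025
MFCC_HOP_S = 0.010
MFCC_N_FILTERS = 26
MFCC_N_COEFFS = 13


def signal_entropy(frame: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of the amplitude occurrence histogram.

    Amplitudes are binned over [-1, 1] (the pipeline normalizes frames
    into that range); empty bins contribute 0 via the 0·log 0 := 0
    convention.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    counts, _ = np.histogram(np.clip(frame, -1, 1), bins=bins, range=(-1, 1))
    p = counts[counts > 0] / frame.size
    return float(-np.sum(p * np.log2(p)))


def homomorphic_envelope(frame: np.ndarray, fs: float = WORKING_FS) -> np.ndarray:
    """Smooth positive amplitude envelope: exp(LP(ln |analytic signal|))."""
    frame = np.asarray(frame, dtype=float)
    analytic = np.abs(hilbert(frame))
    b, a = butter(2, ENVELOPE_LP_HZ, btype="low", fs=fs)
    smoothed = filtfilt(b, a, np.log(analytic + EPS))
    return np.exp(smoothed)


def _normalized_autocorr(x: np.ndarray) -> np.ndarray:
    x = x - np.mean(x)
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    if ac[0] <= 0:
        return np.zeros(n)
    return ac / ac[0]


def _highest_peak_lag(ac: np.ndarray, lo: int, hi: int) -> tuple[int, bool]:
    """Lag of the highest local maximum of ``ac`` in [lo, hi].

    Falls back to the plain argmax over the window (flagged) when no
    local maximum exists there.
    """
    hi = min(hi, len(ac) - 1)
    peaks, _ = find_peaks(ac)
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    if len(peaks):
        return int(peaks[np.argmax(ac[peaks])]), False
    window = ac[lo : hi + 1]
    return lo + int(np.argmax(window)), True


def cycle_and_systole(frame: np.ndarray, fs: float = WORKING_FS) -> tuple[float, float]:
    """Heart rate (bpm) and systolic interval (s) from the envelope
    autocorrelation.

    The cycle duration T is the lag of the highest autocorrelation peak
    in the 0.5-2.0 s window (heart rate = 60/T, so 30-120 bpm); the
    systolic interval is the lag of the highest peak between 0.2 s and
    T/2.
    """
    env = homomorphic_envelope(frame, fs)
    ac = _normalized_autocorr(env)
    lo = int(round(CYCLE_LAG_WINDOW[0] * fs))
    hi = int(round(CYCLE_LAG_WINDOW[1] * fs))
    cycle_lag, _ = _highest_peak_lag(ac, lo, hi)
    t_cycle = cycle_lag / fs
    s_lo = int(round(SYSTOLE_MIN_LAG * fs))
    s_hi = max(int(round(t_cycle / 2 * fs)), s_lo)
    sys_lag, _ = _highest_peak_lag(ac, s_lo, s_hi)
    return 60.0 / t_cycle, sys_lag / fs


def spectral_features(frame: np.ndarray, fs: float = WORKING_FS) -> dict:
    """Power-spectrum summary of the raw (rectangular-windowed) frame.

    Uses the one-sided DFT; ``norm_spectral_entropy`` is the Shannon
    entropy of the power distribution over spectral bins divided by
    log2 of the bin count, so it lies in [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    power = np.abs(rfft(frame)) ** 2
    freqs = rfftfreq(len(frame), d=1.0 / fs)
    total = power.sum()
    if total == 0:
        return {
            "max_power": 0.0,
            "dominant_freq": 0.0,
            "max_spectrum_ratio": 0.0,
            "norm_spectral_entropy": 0.0,
        }
    k = int(np.argmax(power))
    q = power / total
    qp = q[q > 0]
    entropy = -np.sum(qp * np.log2(qp))
    return {
        "max_power": float(power[k]),
        "dominant_freq": float(freqs[k]),
        "max_spectrum_ratio": float(power[k] / total),
        "norm_spectral_entropy": float(entropy / np.log2(len(power))),
    }


def statistical_features(frame: np.ndarray) -> dict:
    """Nine order/moment statistics with bias-adjusted higher moments.

    Skewness is the adjusted Fisher-Pearson form
    N/((N-1)(N-2)) Σ((x-x̄)/s)³ with the sample SD s; kurtosis is the
    matching bias-adjusted excess form (0 for a Gaussian). Both are
    defined as 0 for a constant frame.
    """
    x = np.asarray(frame, dtype=float)
    if x.size < 4:
        raise ValueError("statistical features require at least 4 samples")
    sd = float(np.std(x, ddof=1))
    q1, q3 = (float(v) for v in np.percentile(x, [25, 75]))
    out = {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": sd,
        "mad": float(np.mean(np.abs(x - np.mean(x)))),
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
    }
    if sd == 0:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["skewness"] = float(_skew(x, bias=False))
        out["kurtosis"] = float(_kurtosis(x, fisher=True, bias=False))
    return out


def _band_entropy(coeffs: np.ndarray) -> float:
    energy = coeffs**2
    total = energy.sum()
    if total == 0:
        return 0.0
    p = energy[energy > 0] / total
    return float(-np.sum(p * np.log2(p)))


def wavelet_entropies(frame: np.ndarray, wavelet: str = "db5") -> dict:
    """Shannon entropy of normalized coefficient energies, 4-level db5.

    Bands reported: approximation at level 4 and details at levels 4, 3
    and 2 (the level-1 detail band is dominated by out-of-band noise at
    2 kHz and is not part of the feature set).
    """
    coeffs = pywt.wavedec(np.asarray(frame, dtype=float), wavelet, level=4, mode="symmetric")
    a4, d4, d3, d2, _d1 = coeffs
    return {
        "wentropy_a4": _band_entropy(a4),
        "wentropy_d4": _band_entropy(d4),
        "wentropy_d3": _band_entropy(d3),
        "wentropy_d2": _band_entropy(d2),
    }


def mel_scale(f):
    """Mel value of frequency f (Hz): 1127 ln(1 + f/700)."""
    return 1127.0 * np.log(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (np.exp(np.asarray(m, dtype=float) / 1127.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float) -> np.ndarray:
    """Triangular Mel filterbank spanning 0..fs/2, shape (n_filters, nfft//2+1)."""
    mel_pts = np.linspace(mel_scale(0.0), mel_scale(fs / 2), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.arange(nfft // 2 + 1) * fs / nfft
    fb = np.zeros((n_filters, len(bin_freqs)))
    for i in range(n_filters):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - left) / max(center - left, EPS)
        down = (right - bin_freqs) / max(right - center, EPS)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc_features(frame: np.ndarray, fs: float = WORKING_FS) -> dict:
    """Mean Mel-frequency cepstral coefficients c0..c12 over the frame.

    Per 25 ms window (10 ms hop): Hamming taper, FFT power spectrum,
    26-filter triangular Mel filterbank (Mel(f) = 1127 ln(1+f/700)),
    log energies floored at 1e-10, orthonormal DCT-II. The 13 reported
    scalars are the per-coefficient means over all windows.
    """
    frame = np.asarray(frame, dtype=float)
    win = int(round(MFCC_WINDOW_S * fs))
    hop = int(round(MFCC_HOP_S * fs))
    if len(frame) < win:
        raise ValueError("frame shorter than one MFCC analysis window")
    nfft = int(2 ** np.ceil(np.log2(win)))
    window = np.hamming(win)
    fb = mel_filterbank(MFCC_N_FILTERS, nfft, fs)
    starts = range(0, len(frame) - win + 1, hop)
    coefs = np.empty((len(starts), MFCC_N_COEFFS))
    for j, s in enumerate(starts):
        seg = frame[s : s + win] * window
        power = np.abs(rfft(seg, n=nfft)) ** 2
        mel_energy = fb @ power
        log_energy = np.log(np.maximum(mel_energy, EPS))
        coefs[j] = dct(log_energy, type=2, norm="ortho")[:MFCC_N_COEFFS]
    means = coefs.mean(axis=0)
    return {name: float(v) for name, v in zip(MFCC_FEATURES, means)}


def extract_features(frame: np.ndarray, fs: float = WORKING_FS) -> dict:
    """All 33 scalar features of one frame, keyed by FEATURE_NAMES."""
    hr, systole = cycle_and_systole(frame, fs)
    out = {"signal_entropy": signal_entropy(frame), "heart_rate": hr, "systolic_interval": systole}
    out.update(spectral_features(frame, fs))
    out.update(statistical_features(frame))
    out.update(wavelet_entropies(frame))
    out.update(mfcc_features(frame, fs))
    assert list(out) == FEATURE_NAMES
    return out
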