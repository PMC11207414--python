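"""Synthetic phonocardiogram generator.

Builds annotated heart-sound signals with a known heart rate, systolic
interval and class archetype so that every downstream stage (spike
removal, denoising, framing, feature extraction, classification) can be
exercised and verified without external recordings.

The model is deliberately simple: S1 and S2 are Gaussian-windowed tone
bursts placed at the start of systole and of diastole, murmurs are
band-limited noise gated into the systolic interval, spikes are short
high-amplitude transients, and background noise is white Gaussian noise
calibrated to an exact signal-to-noise ratio against the stored clean
reference. It makes no claim of hemodynamic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import WORKING_FS, AudioSignal, Manifest, write_manifest, write_wav

CLASSES = ("Normal", "CAD", "MVP", "Benign")
"""The four-class label set (multiclass task)."""

BINARY_CLASSES = ("Normal", "Pathologic")


@dataclass
class SynthParams:
    """Parameters of one synthetic heart-sound signal."""

    duration: float = 10.0
    heart_rate: float = 75.0
    systole_fraction: float = 0.35
    s1_freq: float = 60.0
    s2_freq: float = 120.0
    s1_dur: float = 0.06
    s2_dur: float = 0.04
    murmur_band: tuple | None = None
    murmur_gain: float = 0.0
    spike_count: int = 0
    spike_amp: float = 0.0
    noise_snr_db: float | None = None
    seed: int = 0
    fs: float = WORKING_FS

    def validate(self) -> None:
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must be in (0, 1)")
        cycle = 60.0 / self.heart_rate
        if self.s1_dur >= cycle or self.s2_dur >= cycle:
            raise ValueError("burst duration must be shorter than the cycle")
        for f in (self.s1_freq, self.s2_freq):
            if f >= self.fs / 2:
                raise ValueError(f"frequency {f} Hz at or above Nyquist")
        if self.murmur_band is not None and self.murmur_band[1] >= self.fs / 2:
            raise ValueError("murmur band extends to or above Nyquist")


@dataclass
class GroundTruth:
    """What the generator knows about a synthetic signal."""

    heart_rate: float
    systolic_interval: float
    class_label: str = ""
    clean_reference: np.ndarray = field(default=None, repr=False)
    spike_positions: list = field(default_factory=list)


def _tone_burst(t: np.ndarray, center: float, freq: float, dur: float) -> np.ndarray:
    # Gaussian window with sigma = dur/4 (~95% of energy inside dur)
    env = np.exp(-0.5 * ((t - center) / (dur / 4.0)) ** 2)
    return env * np.sin(2 * np.pi * freq * (t - center))


def synth_heart_sound(params: SynthParams) -> tuple[AudioSignal, GroundTruth]:
    """Generate one synthetic PCG signal with its ground truth.

    Deterministic for a fixed ``params.seed``. The clean reference
    (before spikes and noise) is stored in the returned ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    cycle = 60.0 / params.heart_rate
    systole = params.systole_fraction * cycle

    clean = np.zeros(n)
    n_cycles = int(np.ceil(params.duration / cycle)) + 1
    for k in range(n_cycles):
        t1 = k * cycle + params.s1_dur / 2  # S1 at systole onset
        t2 = k * cycle + systole + params.s2_dur / 2  # S2 at diastole onset
        if t1 - 3 * params.s1_dur < params.duration:
            clean += _tone_burst(t, t1, params.s1_freq, params.s1_dur)
        if t2 - 3 * params.s2_dur < params.duration:
            clean += 0.7 * _tone_burst(t, t2, params.s2_freq, params.s2_dur)

    if params.murmur_band is not None and params.murmur_gain > 0:
        noise = rng.standard_normal(n)
        low, high = params.murmur_band
        sos = butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        murmur = sosfiltfilt(sos, noise)
        murmur /= max(np.std(murmur), 1e-12)
        gate = np.zeros(n)
        for k in range(n_cycles):
            a = int(round((k * cycle + params.s1_dur) * fs))
            b = int(round((k * cycle + systole) * fs))
            gate[max(a, 0) : min(b, n)] = 1.0
        clean += params.murmur_gain * murmur * gate

    peak = np.max(np.abs(clean))
    if peak > 0:
        clean = clean / peak * 0.9  # headroom for spikes/noise quantization

    truth = GroundTruth(
        heart_rate=params.heart_rate,
        systolic_interval=systole,
        clean_reference=clean.copy(),
    )
    samples = clean.copy()

    sig = AudioSignal(samples=samples, fs=fs, signal_id=f"synth-{params.seed}")
    if params.spike_count > 0:
        sig = add_spikes(
            sig, params.spike_count, params.spike_amp, seed=int(rng.integers(2**31))
        )
        truth.spike_positions = list(sig.subject_meta.get("spike_positions", []))

    if params.noise_snr_db is not None:
        noise = rng.standard_normal(n)
        sig_power = np.sum(clean**2)
        target_noise_power = sig_power / 10 ** (params.noise_snr_db / 10)
        noise *= np.sqrt(target_noise_power / np.sum(noise**2))
        sig = sig.with_samples(sig.samples + noise)

    m = np.max(np.abs(sig.samples))
    if m > 1.0:  # keep within WAV range; rescale truth identically
        sig = sig.with_samples(sig.samples / m)
        truth.clean_reference = truth.clean_reference / m
    return sig, truth


# Archetype parameter draws: spectrally distinct classes so that the
# feature set separates them. Heart rate and systole fraction vary per
# seed within physiological ranges.
def _archetype_params(class_label: str, rng: np.random.Generator, duration: float) -> SynthParams:
    hr = float(rng.uniform(55, 115))
    sf = float(rng.uniform(0.3, 0.4))
    base = dict(
        duration=duration,
        heart_rate=hr,
        systole_fraction=sf,
        s1_freq=float(rng.uniform(50, 70)),
        s2_freq=float(rng.uniform(100, 140)),
        noise_snr_db=float(rng.uniform(18, 25)),
        seed=int(rng.integers(2**31)),
    )
    if class_label == "Normal":
        return SynthParams(**base, murmur_band=None, murmur_gain=0.0)
    if class_label == "CAD":  # low-band holosystolic murmur
        return SynthParams(
            **base,
            murmur_band=(80.0, 200.0),
            murmur_gain=float(rng.uniform(0.5, 0.8)),
        )
    if class_label == "MVP":  # mid-systolic click + late murmur band
        p = SynthParams(
            **base,
            murmur_band=(250.0, 450.0),
            murmur_gain=float(rng.uniform(0.35, 0.6)),
        )
        return p
    if class_label == "Benign":  # soft wide-band murmur, may reach 1 kHz
        return SynthParams(
            **base,
            murmur_band=(150.0, 990.0),
            murmur_gain=float(rng.uniform(0.2, 0.4)),
        )
    raise ValueError(f"unknown class label {class_label!r}")


def synth_class_signal(
    class_label: str, seed: int, duration: float = 10.0
) -> tuple[AudioSignal, GroundTruth]:
    """Generate a signal from one of the four class archetypes."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")
    rng = np.random.default_rng(seed)
    params = _archetype_params(class_label, rng, duration)
    sig, truth = synth_heart_sound(params)
    if class_label == "MVP":
        # add the mid-systolic click: a short high-frequency transient
        # in each systole, placed at 60% of the systolic interval
        fs = sig.fs
        n = len(sig.samples)
        t = np.arange(n) / fs
        cycle = 60.0 / truth.heart_rate
        click = np.zeros(n)
        k = 0
        while k * cycle < duration:
            c = k * cycle + 0.6 * truth.systolic_interval
            click += 0.5 * _tone_burst(t, c, 300.0, 0.015)
            k += 1
        sig = sig.with_samples(np.clip(sig.samples + click, -1, 1))
        truth.clean_reference = truth.clean_reference + click
    truth.class_label = class_label
    sig.label = class_label
    return sig, truth


def add_spikes(
    signal: AudioSignal, spike_count: int, spike_amp: float, seed: int = 0
) -> AudioSignal:
    """Superimpose short (<10 ms) high-amplitude transients.

    Positions are drawn uniformly (seeded) and recorded in
    ``subject_meta['spike_positions']``. ``spike_count == 0`` is the
    identity.
    """
    if spike_count == 0:
        return signal
    rng = np.random.default_rng(seed)
    fs = signal.fs
    n = len(signal.samples)
    width = int(0.006 * fs)  # 6 ms triangular transient
    if n <= 2 * width:
        raise ValueError("signal too short to place spikes")
    out = signal.samples.copy()
    positions = sorted(int(p) for p in rng.integers(width, n - width, size=spike_count))
    tri = 1.0 - np.abs(np.linspace(-1, 1, 2 * width + 1))
    for pos in positions:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[pos - width : pos + width + 1] += sign * spike_amp * tri
    new = signal.with_samples(out)
    new.subject_meta = dict(signal.subject_meta)
    new.subject_meta["spike_positions"] = positions
    return new


def synth_dataset(
    n_per_class: int,
    classes: tuple = CLASSES,
    duration_range: tuple = (10.0, 30.0),
    seed: int = 0,
) -> tuple[list[AudioSignal], Manifest]:
    """Generate a balanced labeled signal set with its manifest."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not classes:
        raise ValueError("class list must be non-empty")
    rng = np.random.default_rng(seed)
    signals, entries = [], []
    for label in classes:
        for i in range(n_per_class):
            duration = float(rng.uniform(*duration_range))
            sig, truth = synth_class_signal(label, seed=int(rng.integers(2**31)), duration=duration)
            sig.signal_id = f"{label.lower()}-{i:03d}"
            signals.append(sig)
            entries.append(
                {
                    "path": f"{sig.signal_id}.wav",
                    "signal_id": sig.signal_id,
                    "label": label,
                    "subject_meta": {},
                    "_truth": truth,
                }
            )
    manifest = Manifest(entries=entries)
    return signals, manifest


def export_dataset(signals, manifest, out_dir):
    """Write WAVs, a manifest CSV and per-signal ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sig, entry in zip(signals, manifest.entries):
        write_wav(sig, out_dir / f"{sig.signal_id}.wav")
        truth = entry.get("_truth")
        if truth is not None:
            side = {
                "heart_rate": truth.heart_rate,
                "systolic_interval": truth.systolic_interval,
                "class_label": truth.class_label,
            }
            (out_dir / f"{sig.signal_id}.json").write_text(json.dumps(side, indent=1))
    clean_entries = [
        {k: e[k] for k in ("path", "signal_id", "label", "subject_meta")}
        for e in manifest.entries
    ]
    write_manifest(Manifest(entries=clean_entries), out_dir / "manifest.csv")
    return out_dir
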