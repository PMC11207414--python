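# Methods

This note records the models, the numerical choices, and what the
synthetic data can and cannot demonstrate.

## Signal model and preprocessing

All processing happens at fs = 2 kHz; input audio at other rates is
resampled on ingest with a polyphase antialiasing filter
(`scipy.signal.resample_poly`). Amplitudes are dimensionless in [−1, 1].

**Spike removal.** The recording is divided into 0.5 s windows (a
trailing partial window is kept; a 1-sample tail is merged into the
previous window). Each window's maximum absolute amplitude (MAA) is
recorded; while any MAA exceeds 3 × median(MAA), the window with the
largest MAA (ties: earliest) is selected, and samples between the last
zero-crossing before the maximum and the first after it are zeroed. If a
window contains no zero-crossing on one side, the search extends across
the whole signal, falling back to the window boundary. A hard iteration
cap (1000) guarantees termination; hitting it flags the output instead
of raising. The procedure is idempotent: once the stopping criterion
holds, a second pass is the identity.

**Wavelet denoising.** Multilevel DWT (db5, level 6, symmetric
extension), soft thresholding of every detail band at the universal
threshold t_j = σ_j √(2 ln N) with N the signal length and
σ_j = median(|d_j|)/0.6745 the per-level robust noise estimate;
approximation coefficients pass through; reconstruction is trimmed to
the input length. A zero estimated σ_j leaves that band untouched.
Known behaviour worth stating plainly: soft thresholding shrinks every
retained coefficient by t_j, so for signals whose energy sits in short
tone bursts (exactly the S1/S2 structure of a heart sound) there is an
irreducible reconstruction bias. On the bundled noisy suite this caps
the measured SNR improvement at roughly 5–6 dB for 0 dB input and
2–3.5 dB for 10 dB input. The per-level estimate is also biased upward
when a sustained narrowband component occupies an entire band — a pure
sine is the pathological case and will be attenuated, not recovered.
The grid-search utility (`optimize_denoise`) ranks configurations by
mean output SNR against known clean references; which wavelet wins
depends on the data, and on the synthetic burst fixtures sym6 typically
edges out db5.

**Bandpass and normalization.** Zero-phase (forward–backward) 4th-order
Butterworth, 25–450 Hz, implemented with second-order sections for
numerical stability; the effective magnitude response is squared.
Binary-mode chains apply it; multiclass chains skip it so murmur content
up to ~1 kHz survives. The last stage scales to unit peak; an all-zero
signal passes through with a warning rather than dividing by zero.

**SNR.** Defined only against a known clean reference:
snr = 10·log10(Σr² / Σ(x−r)²), capped at 300 dB for a zero residual.
No blind SNR estimator is provided; on real recordings without a
reference the quantity is simply not computable by this package.

## Features (33 per 5 s frame)

* Amplitude entropy: Shannon entropy of a 64-bin histogram over [−1, 1]
  (frames are normalized upstream), in bits.
* Heart rate and systolic interval: homomorphic envelope
  exp(LP(ln|analytic signal| + 1e−10)) with a 2nd-order zero-phase 8 Hz
  low-pass; autocorrelation of the mean-removed envelope normalized at
  lag 0; cycle duration T = lag of the highest local maximum in
  [0.5 s, 2.0 s] (plain argmax fallback when no local maximum exists),
  HR = 60/T bpm; systolic interval = highest-peak lag in [0.2 s, T/2].
  The lag window confines HR to [30, 120] bpm by construction.
* Spectral: one-sided DFT power of the raw (rectangular) frame;
  maximum, its frequency, max/total ratio, and Shannon entropy of the
  power distribution normalized by log2(#bins). An all-zero frame
  returns zeros with a flag.
* Statistics: mean, median, sample SD (N−1), mean absolute deviation,
  Q1, Q3 (linear-interpolated percentiles), IQR, adjusted Fisher–Pearson
  skewness and adjusted excess kurtosis (both 0 for a constant frame).
* Wavelet entropies: 4-level db5; for each of A4, D4, D3, D2 the
  Shannon entropy of p_k = c_k²/Σc². D1 (500–1000 Hz) is excluded from
  the feature set. The db5 family matches the denoiser.
* MFCC: 25 ms window, 10 ms hop, Hamming taper, 64-point FFT power,
  26 triangular filters spanning 0–1000 Hz on the 1127·ln(1+f/700)
  scale, log energies floored at 1e−10, orthonormal DCT-II; the 13
  reported scalars are the per-coefficient means over all windows in the
  frame, and "mfcc_1" is the energy-like c0.

## Dataset construction

Framing: 5 s window, 1 s shift, count = floor((n − w)/s) + 1 in sample
units; sub-window tails are discarded. Balancing removes excess frames
per class uniformly at random (seeded) down to the minimum class count.
Frame-level splits take floor(0.8·n) training rows per class (remainder
to test) after a seeded shuffle; signal-level splits partition whole
signals 80/20 per class first, then frame and balance each side
independently, and assert the no-shared-signal invariant on every
build. Excess-frame removal runs after feature extraction, which is
simpler and deterministic. Stratified 10-fold indices are available for
cross-validation.

## Classifiers

All presets standardize features with training-set mean/SD (constant
features map to 0). k-NN uses city-block or Euclidean distance with
equal, inverse-distance, or squared-inverse-distance vote weights; a
zero-distance neighbour takes the whole vote (the limit of 1/d^p). The
SVM uses the scaled cubic polynomial kernel ((x/s)·(y/s) + 1)³ with box
constraint C = 1; "automatic" kernel scale s is the median pairwise
Euclidean distance on (a ≤500-row subsample of) the standardized
training data — a stand-in for an unpublished vendor heuristic, so
numerical parity with tools using that heuristic is not claimed. SVM
scores are Platt-calibrated probabilities (seeded). Networks are fully
connected ReLU stacks (e.g. 200-100-50) trained full-batch with L-BFGS,
L2 penalty λ, iteration cap 1000, softmax outputs. Model size is the
length of the canonical pickle — informative for comparing families,
not comparable across serialization formats.

## Evaluation

Binary metrics take "Pathologic" as the positive class by default
(sensitivity = disease detection). 0/0 ratios are defined as 0 and
flagged, never NaN. Multiclass metrics are micro-averaged; for
single-label problems ΣFP = ΣFN = the off-diagonal total, hence
micro P = micro Se = Acc exactly (property-tested). ROC curves group
tied scores into one threshold step, so trapezoidal AUC equals the
concordant-pair (Mann–Whitney) statistic with ties counted ½.
Percentages are rendered at one decimal (half-up) only at presentation;
raw fractions are retained.

## Synthetic generator

S1 is a Gaussian-windowed tone (~60 ms, 50–70 Hz) at each cycle start;
S2 (~40 ms, 100–140 Hz, 0.7 relative amplitude) at the end of systole
(systolic fraction 0.30–0.40 of the cycle). Murmurs are band-limited
Gaussian noise gated into systole: CAD-like 80–200 Hz, MVP-like
250–450 Hz plus a mid-systolic click, benign-like soft and wide-band up
to 990 Hz (which exercises the no-bandpass multiclass path); Normal has
none. Spikes are 6 ms triangular transients at seeded positions.
Additive noise is white Gaussian scaled to an exact target SNR against
the stored clean reference. Every call draws from one seeded generator;
identical seeds give bit-identical output.

What the generator does **not** emulate: respiratory and friction
noise, sensor coupling variation, heart-rate variability within a
recording, S3/S4 sounds, diastolic murmurs, and the acoustic diversity
of real patients. Passing tests therefore demonstrate that the
machinery is correct and the archetypes are learnable — not that
clinical accuracy would match. The synthetic classes are far more
separable than real recordings; nearest-neighbour classifiers routinely
reach 100% on them.

## Problem sizes and determinism

Test and demo sizes are deliberately desk-scale: demos use 3–10 signals
per class of 6–15 s; the acceptance script uses 100 signals for
heart-rate recovery, 20 for the denoising suite, and 10/6 signals per
class for the binary/multiclass end-to-end runs. Durations 5–120 s and
arbitrarily many signals are supported; costs grow linearly in total
audio length. All stages are deterministic given the configured seeds;
feature extraction is pure.

## Known limitations

* The denoiser's measured improvement on burst-like signals is modest
  (see above); hard thresholding would measure better but is not the
  configured method.
* Heart-rate estimation assumes a quasi-periodic envelope; on noise or
  arrhythmic patterns the windowed argmax fallback still returns a
  value in [30, 120] bpm, flagged upstream only by implausible feature
  combinations.
* The multiclass micro-average hides per-class behaviour; inspect the
  confusion matrix and per-class AUC for class-wise claims.
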