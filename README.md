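# heartframe

Segmentation-free classification of heart sounds (phonocardiograms,
PCG). Auscultation is one of the cheapest ways to screen for valvular
and coronary disease, but most automated PCG classifiers first segment
each beat into S1/systole/S2/diastole — a step that is computationally
heavy and often needs a simultaneous ECG. `heartframe` implements the
alternative: skip segmentation entirely, cut each recording into
overlapping 5 s frames, describe every frame with 33 scalar features,
and feed those to small classifiers (k-NN, cubic-kernel SVM,
feed-forward ReLU networks) that fit on embedded hardware.

It is aimed at biomedical-signal researchers and engineers who want a
tested, reproducible reference pipeline for frame-level PCG
classification, including a synthetic heart-sound generator so the whole
chain can be exercised without any clinical recordings.

## Pipeline

For each mono recording (resampled to fs = 2 kHz):

1. **Spike removal** — split into 0.5 s windows, record each window's
   maximum absolute amplitude (MAA); while any MAA > 3 × median(MAA),
   zero the transient between its bounding zero-crossings.
2. **Wavelet denoising** — db5 decomposition to level 6; each detail
   band `d_j` is soft-thresholded at the universal threshold
   `t_j = σ_j √(2 ln N)` with the robust estimate
   `σ_j = median(|d_j|)/0.6745`.
3. **Bandpass** — zero-phase 4th-order Butterworth, 25–450 Hz. Applied
   only for the binary (Normal/Pathologic) task; the four-class task
   (Normal/CAD/MVP/Benign) keeps the full band because benign murmurs
   can reach ~1 kHz.
4. **Normalization** to unit peak amplitude, then framing: 5 s window,
   1 s shift.

Each frame yields 33 scalars: amplitude-histogram Shannon entropy, heart
rate and systolic interval from the autocorrelation of the homomorphic
envelope (cycle = highest peak lag in 0.5–2 s, so HR = 60/T ∈ [30, 120]
bpm), four one-sided power-spectrum summaries, nine order/moment
statistics (with bias-adjusted skewness and excess kurtosis), Shannon
entropies of the normalized coefficient energies in the A4/D4/D3/D2
bands of a 4-level db5 transform, and the means of MFCCs c0–c12
(25 ms Hamming windows, 26 triangular Mel filters with
Mel(f) = 1127 ln(1 + f/700), orthonormal DCT-II).

Train/test tables are built under two protocols: **frame-level** (pool
frames, balance classes by random removal, split 80/20 per class —
frames of one signal may land in both sets, which leaks) and
**signal-level** (split whole signals 80/20 first, then frame and
balance each side — leakage-free, the realistic new-patient protocol).

Metrics follow the screening conventions: Acc, Se, Sp, P,
BA = (Se+Sp)/2, F1 = 2·P·Se/(P+Se), micro-averaged for the multiclass
task (which makes micro P = micro Se = Acc for single-label problems),
plus one-vs-all ROC AUC and the serialized model size.

## Worked example

The self-contained four-class demo (24 synthetic signals, 6 per class,
8–12 s each, frame-level split, 1-NN with city-block distance):

```sh
heartframe --quiet run-all --mode multiclass --preset k-NN1-M --n-per-class 6 --seed 7
```

prints the test-set metrics as percentages:

```json
{"accuracy": 100.0, "balanced_accuracy": 100.0, "f1": 100.0,
 "precision": 100.0, "sensitivity": 100.0, "specificity": 100.0}
```

On this small, well-separated synthetic set the 24-frame test confusion
matrix is diagonal (6 frames per class, all correct), the per-class AUC
is 1.0, and the pickled model occupies ~25 kB. Accuracy, precision and
sensitivity coincide exactly — that is the micro-averaging identity, not
a coincidence. Real recordings are far harder than the synthetic
archetypes; perfect scores here say the pipeline is wired correctly, not
that clinical performance would be perfect.

Each stage is also available on its own (`simulate`, `preprocess`,
`extract`, `split`, `train`, `evaluate`) and as library functions; see
`docs/methods.md` for the model and its assumptions.

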