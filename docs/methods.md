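# Methods

This note documents the models, numerical choices and known limitations of
the `beatmeter` package.  Nothing here states a result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Stimulus model

Stimuli are isochronous streams of short complex tones with a 300 ms
inter-onset interval (3.33 Hz beat).  Meter is imposed purely by intensity
accents: the strong tone is the weak tone amplified by `accent_db`
decibels on amplitude, `10**(accent_db/20)`; the default +10 dB gives an
amplitude factor of 3.162.  Duple meter accents every 2nd beat
(inter-strong interval 600 ms → 1.67 Hz), triple every 3rd (900 ms →
1.11 Hz).

The tone is a deterministic damped harmonic complex: fundamental 220 Hz
(A3), 100 ms duration, 8 harmonics with 1/k amplitudes, exponential decay
τ = 40 ms, 5 ms raised-cosine onset ramp, synthesized at 22 050 Hz.  This
replaces sampled instrument timbres on purpose: the synthesis is exactly
reproducible, and the *locations* of the envelope-spectrum peaks are
timbre-invariant (a property test sweeps tone models), even though the
peak power *ratios* are not.  For that reason the envelope beat-to-meter
ratios of the synthetic stimuli (≈2.96 duple, ≈2.45 triple, printed by
`beatmeter make-stimulus`) are properties of this timbre and envelope
definition, not reproductions of any particular recorded stimulus pair.

A "~10 s" stimulus is realized as whole measures: duple 16 measures
(32 beats, 9.6 s), triple 11 measures (33 beats, 9.9 s), keeping the meter
periodicity exact.  After synthesis the waveform is RMS-normalised to the
0.01 reference.

The **amplitude envelope** is the analytic-signal (Hilbert) magnitude
low-passed at 30 Hz with a zero-phase 4th-order Butterworth — this
isolates rhythm-band energy from the audio carrier.  Rectify-and-smooth
would be an acceptable alternative; one definition had to be fixed and
this is it.

**Spectra** are one-sided power spectra on a grid of exact integer
multiples of the requested resolution: the signal is zero-padded to the
next integer multiple of `1/resolution` seconds and only the lattice bins
are kept.  For the stimulus characterisation the pattern is tiled to
120 s and analysed at 0.01 Hz resolution, which puts the expected peaks at
the grid points 3.33, 1.67 and 1.11 Hz (nearest 0.01 multiples of 10/3,
5/3 and 10/9).

## Frequency-tagging chain

* **Filtering** — zero-phase 4th-order Butterworth band-pass 0.1–40 Hz
  applied forward-backward (filter order/type is a package choice).  The
  0.1 Hz corner rings for seconds, so `filtfilt` padding is scaled to
  3/lo_hz; gains are within ±1% at 1–10 Hz in the interior of a block.
* **Epoching** — windows −1 to 11 s around each stimulus onset, half-open
  in samples; epochs that would cross a recording edge are dropped with a
  logged count; the evoked response is the plain arithmetic mean.
* **Welch PSD, 0.05 Hz lattice** — a 12 s evoked trace natively gives
  1/12 ≈ 0.083 Hz spacing, which cannot represent a 0.05 Hz grid.  The
  package therefore uses a single Hann-windowed segment spanning the full
  trace, zero-padded to 20 s equivalent so every FFT bin is an exact
  multiple of 0.05 Hz.  Multi-segment averaging would coarsen the
  resolution below the target and is not used.  On this lattice the bin
  nearest the 3.333 Hz beat is **3.35 Hz** and the bin nearest the
  1.667 Hz duple meter is **1.65 Hz** (both asserted in tests).  For the
  triple meter, 1.111 Hz falls nearest the **1.10 Hz** bin; a study that
  reports a triple meter peak at 1.11 Hz cannot have used a fixed 0.05 Hz
  lattice for that condition, so this package documents 1.10 as its
  expected triple-bin and does not assert otherwise.
* **Peaks and ratio** — the peak is the maximum bin within the closed band
  (beat 3.2–3.5 Hz; meter 1.6–1.9 or 1.0–1.4 Hz), no interpolation, ties
  to the lower frequency.  Per-channel PSDs are arithmetically averaged
  before peak extraction; the ratio is invariant to any global sensor
  scaling (tested).

## Cardiac chain

R peaks: 5–15 Hz zero-phase band-pass, derivative, squaring, 150 ms
moving-window integration, candidate maxima with a 250 ms refractory
period, adaptive threshold at a configurable fraction (default 0.3) of a
2 s rolling maximum of the integrated transform, then refinement to the
extremum of the band-passed trace within ±100 ms.  On clean synthetic ECG
the detector's recall and precision are ≥0.99 within ±10 ms, and ≥0.97
recall at 10 dB SNR (tested).  The "manual editing" step of lab practice
is replaced by an explicit corrections list (`add`/`remove` timestamps).

IBIs are successive peak differences in ms; an optional physiological
filter removes intervals outside 300–2000 ms and is **off by default**
(whether any such exclusion should apply is a study-level choice).  RMSSD
is computed over the full condition block with no detrending.

## Synthetic cohort

The generator defines the study conditions the package is tested under:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 15 | cohort size |
| `conditions` | rest, duple, triple | 5 min rest ECG; ~6 min task blocks |
| `n_reps` / `gap_s` | 30 / 2.0 | stimulus repetitions per block and gaps |
| `fs_neural_hz`, `fs_ecg_hz` | 1000 | sampling rates |
| `n_channels` | 20 | homogeneous sensor channels |
| `mu_log10_ratio` | log10(2.48) | cohort mean of the latent log ratio |
| `sd_log10_ratio` | 0.21 | between-subject SD (matches a ratio CV of ~0.5 around a mean of ~2.5) |
| `mean_ibi_ms` | 850 | mean inter-beat interval |
| `snr_single_epoch_db` | −10 | single-epoch, single-channel evoked SNR |
| `noise_exponent` | 1.0 | sensor-noise 1/f slope (plus a 10% white floor) |
| `rest_rmssd_offset_ms` | 6.3 | rest RMSSD above the subject's mean task RMSSD |

Each repetition contributes two sinusoids phase-locked to the stimulus
onset — beat at 10/3 Hz and meter at 5/3 (duple) or 10/9 Hz (triple) —
with `(A_beat/A_meter)² = 10**log10_ratio` and `A_meter = 1`.  Channel
noise is 1/f^1 with a white floor, scaled so that the single-epoch SNR
(component power over noise power) is −10 dB: the raw signal is buried in
noise, and evoked averaging over the repetitions is what makes the peaks
legible — with the default 30 repetitions and 20 channels the
end-to-end recovery error of log10(ratio) has a median well inside the
±0.05 design bound (tested over 20 seeds).

IBI series are `mean + x` with `x` stationary Gaussian (AR(1) optional);
the marginal SD is set from the closed form `SD(diff) = s·sqrt(2(1−φ))` so
the realized RMSSD matches its target (within 5% on 5-min series, tested,
converging with duration).  The ECG render places a Mexican-hat QRS
transient at each beat plus baseline wander and white noise at a
configurable SNR, returning ground-truth peak times.

The latent coupling is generated on the log10 scale:
`log10(RMSSD) = intercept + slope·log10(ratio) + ε`.  Two profiles ship:
`duple` (slope −0.56, intercept 1.83, ε calibrated so the latent R² is
0.481) and `triple` (−0.29, 1.74, R² 0.23).  With `sd_log10_ratio` = 0.21
the calibration gives ε SD ≈ 0.122 and 0.111 respectively.  The profile
slope is negative — higher HRV goes with lower beat-to-meter ratio — and
the generator keeps the sign explicit; correlation magnitudes, not signs,
are the design values.  Rest RMSSD has no generative model of its own and
is declared as task mean + offset.

Randomness uses one root `SeedSequence`; per-subject and per-condition
substreams are spawned deterministically, so identical configs are
byte-identical (tested).

## Statistics

* RM-ANOVA: standard one-way within-subject decomposition; Greenhouse–
  Geisser ε from the double-centred condition covariance, applied to both
  dfs; partial η² = SS_cond/(SS_cond+SS_err); post hoc paired t-tests with
  Bonferroni multiply-and-cap.  The implementation is plain numpy and is
  cross-checked against `pingouin.rm_anova` in the tests; its GG-corrected
  type-I error rate at α = .05 over 5 000 null 15×3 tables falls within
  [0.03, 0.07] (tested).  Note the ε-correction is conservative in the
  significance region but can slightly *lower* p when F is near or below
  1; that is the standard behaviour.
* Bootstrap: subjects resampled with replacement (default 1 000 reps),
  percentile 2.5/97.5 interval, seed recorded in the output.
* Regression: OLS of log10(RMSSD) on log10(ratio); log base 10 so the
  intercept is log10(ms).  Non-positive inputs are rejected naming the
  offending index; zero variance raises an explicit degenerate-result
  error rather than returning NaN.
* A generic Wilcoxon signed-rank wrapper is provided for convenience; it
  has no synthetic ground truth of its own.

## Problem sizes used in checks

The acceptance script uses desk-scale versions of the study conditions,
chosen as the smallest sizes at which each quantity is stable: stimulus
spectra from 120 s tilings at 0.01 Hz resolution; grid checks on single
noise-free 12 s evoked traces; coupling-slope recovery on a 200-subject
cohort with 10 repetitions × 4 channels per block and residual coupling
noise SD 0.05 (at that size the slope estimate's sampling SD is ≈0.02,
comfortably inside the ±0.05 recovery bound).  The test suite additionally
runs 20 full-size (30-rep, 20-channel) single-subject recovery checks.

## Limitations

* The synthetic sensor model is deliberately minimal: homogeneous
  channels, pure sinusoidal evoked components, 1/f + white noise.  It
  contains no sensor-type mixing, no artifacts (cardiac, ocular), no head
  movement, and no source geometry — passing tests demonstrate the
  correctness of the analysis chain, not its robustness to real
  recordings' preprocessing needs (tSSS/SSP etc. are out of scope).
* The ECG morphology is a single stereotyped transient; P/T waves,
  ectopics and respiratory sinus arrhythmia are not modelled, so detector
  performance on real ECG will be lower than the synthetic figures.
* Stimulus-level beat-to-meter power ratios depend on timbre and on the
  envelope definition; only peak *locations* are asserted.
* Real-data entry points are text-based (pre-averaged evoked CSV, ECG/IBI
  text); no FIF/EDF ingestion.
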