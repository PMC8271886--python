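# Methods

## Overview

`somnoring` implements a multi-sensor sleep-staging pipeline of the kind
used by ring-format wearables: triaxial accelerometry (50 Hz), finger skin
temperature (0.1 Hz), and inter-beat intervals (IBI) from an optical pulse
sensor are reduced to per-epoch features on the standard 30-s AASM grid,
normalized per night, and classified into sleep stages with a
gradient-boosted tree ensemble. Two stage vocabularies are supported:
wake/sleep and wake/light/deep/REM (light = N1+N2, deep = N3). Evaluation
follows the standardized device-validation framework: epoch-by-epoch
sensitivity/specificity per stage plus Bland-Altman agreement of stage
durations with data-driven bias and limits-of-agreement (LoA) models.

Because clinical polysomnography datasets of this kind are proprietary, the
package ships a stage-conditioned night simulator that serves as the study
population for every test. All quantitative statements in the test suite
are statements about this synthetic population, not about real sleep.

## Feature extraction

**Accelerometer.** Three families per 30-s epoch:

1. *Band-passed descriptives.* Each axis is filtered with a 5th-order
   Butterworth band-pass, 3–11 Hz, and rectified; per epoch we take the
   10%-trimmed mean (drop ⌊0.1·n⌋ samples per side after sorting), the max,
   and the interquartile range (IQR, p75−p25 with linear interpolation,
   computed on the untrimmed epoch). Filtering is zero-phase
   (forward–backward) so movement energy stays aligned with its epoch; the
   offline setting makes the non-causal filter appropriate. Segments
   shorter than the filter warm-up yield missing features.
2. *Mean amplitude deviation (MAD).* On the raw (unfiltered) signal, per
   5-s sub-epoch: MAD = mean |r − mean r| with r the vector magnitude; the
   six MAD values per epoch are summarized by trimmed mean / max / IQR.
   Sub-epochs with under half their samples valid are missing.
3. *Arm angle.* Per 5-s sub-epoch, angle = atan(median z / √(median x² +
   median y²)); the feature is |Δ angle| between successive sub-epochs
   (the first sub-epoch of a night has no predecessor and is missing),
   summarized per epoch as above.

All accelerometer columns additionally receive centered rolling mean and
max smoothing over ±2 and ±10 epochs (±1 and ±5 min), mirroring how human
scorers read context both before and after the current epoch. Windows are
truncated at the night edges and missing-aware.

**Temperature.** Samples outside 31–40 °C are masked (bounds inclusive —
"outside the range" is read strictly); per epoch: mean, min, max, sample
(n−1) standard deviation (needs ≥2 valid samples), and the valid-sample
count. A fully-masked epoch propagates missing values; the classifier
accepts such rows natively.

**IBI quality control.** An interval is *abnormal* when its instantaneous
heart rate deviates by more than 16 bpm from the heart rate of the 7-point
median interval centered on it (windows truncate at record edges; records
shorter than 7 intervals are entirely abnormal). An interval is *usable*
only when it sits inside five consecutive normal intervals (two before,
two after), so the first and last two intervals of a record are never
usable.

**HRV features.** Computed on 1-min and 5-min sliding windows centered on
each epoch midpoint (alignment chosen to match the past-and-future
smoothing philosophy; windows near the night edge are simply truncated and
fail the coverage test when too short). A window needs ≥70% of its span
covered by usable intervals. Time domain: HR = 60000/mean interval, rMSSD,
sample-SD SDNN, pNN50 (successive pairs must be adjacent in the original
record). Frequency domain: the usable tachogram is cubic-spline
interpolated to 4 Hz; Welch PSD (segment length min(window, 256) samples,
50% overlap, linear detrend); LF = [0.04, 0.15) Hz, HF = [0.15, 0.4] Hz
band powers by trapezoidal integration; band peaks as the argmax frequency;
normalized units LF/(LF+HF) and HF/(LF+HF) (the LF/HF ratio is also
emitted); breathing rate = HF peak × 60. LF and total power require the
5-min window's resolution; the 1-min window carries HF-band and time-domain
quantities. Spectral and zero-crossing features are withheld when a window
contains an unusable gap longer than 5 s. Zero-crossing features: mean and
CV (population SD / mean) of the gaps between sign changes of the
mean-centered tachogram slice; fewer than two crossings → missing. Welch's
frequency resolution at 4 Hz with 256-sample segments is 0.0156 Hz, so the
worst-case HF-peak quantization error (±0.008 Hz) sits well inside the
±0.02 Hz recovery tolerance the tests demand.

**Circadian/homeostatic columns.** Three sensor-independent columns per
epoch, parameterized only by night duration: a 24-h cosine phase-anchored
to peak at the night midpoint; exp(−t/τ) with τ = 2 h for the decay of
homeostatic sleep pressure (fastest early, when deep NREM dominates); and
elapsed night fraction in [0, 1]. The cosine anchor and τ are declared
package choices — the shapes, not specific values, are what the features
contribute — and tests assert shape properties only.

## Normalization

Flagged features are re-expressed per night as robust z-scores,
z = (x − median)/(p95 − p5), over the night's non-missing values
(percentiles with linear interpolation; a range below ε = 1e-9 maps
non-missing entries to exactly 0). This removes between-subject baselines
(resting HR, HRV magnitude, skin temperature) while preserving within-night
stage contrasts, and it is idempotent. Exempt from normalization: the
per-axis band-passed maxima and the MAD maximum together with their
smoothed variants (absolute movement magnitude is itself the wake signal),
the circadian columns (scale-fixed by construction), and bookkeeping
count/fraction columns (temperature valid counts, HRV coverage).

## Classification and validation

The stager is a LightGBM classifier with DART boosting and 500 estimators;
missing values are handled natively. Remaining hyperparameters are package
defaults chosen once for noisy wearable features: num_leaves 31, max_bin 63
(coarse histogram binning), learning rate 0.1. Feature sets are nested —
ACC ⊂ ACC+T ⊂ ACC+T+HRV ⊂ ACC+T+HRV+C — to expose each sensor's marginal
value. Cross-validation is 5-fold **grouped by subject**: all nights of a
subject share a fold, so every night is predicted by a model that never saw
that person; this is the conservative reading that prevents identity
leakage.

The permutation-null check (labels permuted, balanced accuracy must sit at
chance = 0.25) is a test of the CV plumbing, not of model capacity, so it
runs with a lighter boosting configuration (gbdt, 100 trees) on a subsample
of epochs; chance level under permuted labels is capacity-independent.

## Evaluation framework

Epoch metrics are computed per night (one-vs-rest accuracy, sensitivity,
specificity per stage, in %) and summarized across nights as mean (SD) with
t-based 95% CIs; pooled overall accuracy and f1 in macro, micro, and
weighted variants are also reported (macro is the headline, the averaging
convention being otherwise ambiguous). For the two-stage scheme,
specificity for wake is identically sensitivity for sleep.

Stage-duration agreement uses a two-branch Bland-Altman model fitted to
per-night minutes: (1) regress difference on reference; slope significant
at p < 0.05 → proportional bias b0 + b1·ref, else constant mean bias;
(2) regress |residuals| on reference; slope significant → heteroscedastic
LoA = bias ± 2.46·(c0 + c1·ref), where 2.46 = 1.96·√(π/2) converts a
fitted mean absolute residual to a 1.96-SD scale under normality, else
LoA = bias ± 1.96·SD. Degenerate inputs (zero-variance differences or
reference) short-circuit to a constant bias with zero-width LoA. At least
10 night pairs are required.

## Synthetic study population

The generator is a pure function of (config, seed) and emits ground truth
for every injected event so filters are scored against truth, not
heuristics.

**Hypnogram.** First-order Markov chain on {wake, light, deep, REM} over
30-s epochs, starting in wake with a short configurable latency.
Transitions *into and within* deep sleep are multiplied by a decaying
weight (scale 3.0, τ = 1.2 h) and REM transitions by a weight rising
linearly from 0.1 to 2.8 across the night, reproducing the early-deep /
late-REM asymmetry of human sleep; explicit 70–120-min cycle machinery is
deliberately omitted (cycles emerge only loosely and are not asserted).
Because the chain is time-inhomogeneous, the occupancy oracle used in tests
is the forward-propagated marginal, not the stationary vector of any single
matrix.

**IBI.** interval = 60000/HR(t) + A(t)·sin(2π f(t) t) + Gaussian noise
(8 ms), with stage-wise means HR = 70/60/56/66 bpm and respiratory
sinus-arrhythmia amplitudes 25/30/15/40 ms for wake/light/deep/REM and
breathing at 0.28/0.25/0.22/0.30 Hz; all stage tracks are smoothed across
boundaries. On top of the stage structure the night carries slow autonomic
dynamics: an NREM HR decline, a stage-independent circadian HR arc (dip up
to ~16 bpm with night-varying depth and timing), a rise of RSA amplitude
and breathing rate toward morning (night-varying slope), and slow random
walks in all three tracks. Ectopic-like artifacts are injected at a
configured per-interval rate, spaced at least 8 intervals apart, with the
interval rescaled to move its instantaneous HR by a target 25–45 bpm — so
every injection violates the 16-bpm rule by construction at any local HR.

**Accelerometer.** Unit gravity vector with posture shifts (random new
orientation, smoothed over ~1 s; more frequent in wake), white sensor noise
(0.005 g), and 3–11 Hz movement bursts (Hann-enveloped sinusoid pairs,
~0.35 g) concentrated in wake epochs; output clipped to the ±2 g sensor
range.

**Temperature.** Saturating rise (τ ≈ 2 h, night-varying speed and span)
from 33.8 to ≈35.2 °C, slow vasomotor waves (SD 0.35 °C, tens of minutes),
white noise 0.06 °C, and optional out-of-range artifact samples drawn
strictly outside [31, 40] °C.

**Cohorts.** Per-subject draws: baseline offsets in HR (SD 4 bpm) and
temperature (SD 0.6 °C), an overall HRV amplitude scale, and — central to
the sensor-ablation behavior — a shared *autonomic coupling* factor scaling
the HR, RSA and breathing stage contrasts together (lognormal, SD 0.5),
with a 40% subpopulation of nearly flat coupling (uniform 0.05–0.35).

**What the generator emulates, and what it does not.** The defaults were
calibrated, before freezing the test suite, so that the synthetic
population reproduces the qualitative structure the pipeline is designed
to exploit: movement identifies wake but not sleep depth; autonomic
features carry most of the staging signal; time-of-night priors add
genuine information because the sensor streams are confounded with time in
night-varying ways (so the circadian columns are the only reliable clock)
and because part of the population shows weak autonomic stage contrast.
Under these conditions the nested feature sets improve monotonically, as
they do on real cohorts. The generator does not model sleep cycles
explicitly, apneas/arousals, age effects, PPG waveform morphology (a
Gaussian-pulse train is provided only to exercise the beat detector), or
scorer disagreement in the reference hypnograms. Passing tests therefore
demonstrate correctness of the pipeline's mechanics and the direction of
its sensor-ablation behavior, not clinical accuracy levels.

## Problem sizes and seeds

Chosen as the package's own desk-scale defaults: the ablation study runs
20 subjects × 1 night of 7 h (16,800 epochs) through full simulation,
extraction, and 5-fold grouped CV with the default DART/500 configuration;
the permutation null uses 20 repeats on a 6,000-epoch subsample; the
artifact-filter check uses 1,000 three-minute IBI records (500 in the
acceptance script); spectral recovery sweeps 0.16–0.39 Hz in 0.01-Hz
steps; temperature masking uses 100 nights; Bland-Altman recovery uses 400
synthetic night pairs with diff = 16 − 0.04·ref and residual SD
5 + 0.01·ref; architecture asymmetry uses 500 simulated hypnograms. All
randomness flows from explicit seeds; `scripts/acceptance.py` derives every
stream from its `--seed` argument.

## Known limitations

- The beat detector is a simple moving-average/peak picker intended for
  clean synthetic PPG; the IBI-file path is the primary tested input.
- The two-branch Bland-Altman procedure uses OLS significance at p < 0.05
  for both branch decisions; small-sample behavior of the heteroscedastic
  branch is untested below ~50 pairs.
- HRV window alignment (centered) and the normalized-power convention
  (normalized units rather than LF/HF only) are declared package choices
  among several defensible readings.
- Synthetic accuracy numbers depend on generator settings and should never
  be quoted as expected device performance.
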