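# Methods

## The measurement chain and its simulation

A hand-held stick with two dry metal handle electrodes records the
Einthoven I lead at 200 Hz. Each hand couples through the stratum corneum
(SC), modelled as a parallel RC pair per electrode; the SC capacitance uses
a cylindrical-capacitor approximation

    C_sc = 2π ε₀ ε_r l_elec / ln((d_elec + d_sc) / d_elec)

with electrode length `l_elec = 4.5 cm`, radius `d_elec = 1.1 cm`, SC
thickness `d_sc` (tens of µm to 800 µm) and relative permittivity `ε_r`
(10³–10⁵ with skin humidity). Over these ranges the model spans roughly
36 nF–280 µF; C_sc is strictly decreasing in `d_sc` and linear in `ε_r` and
`l_elec`.

The amplifier front end adds a series coupling capacitor `C_cpl` into an
input resistance `R_in = 50 GΩ`, a first-order high-pass with
`f_c = 1/(2π R_in C_cpl)` — 0.032 Hz at 100 pF up to 32 Hz at 0.1 pF. The
full divider is

    H(jω) = Z_in / (Z_in + 2·Z_skin + Z_cpl),
    Z_skin = R_sc / (1 + jω R_sc C_sc),  Z_cpl = 1/(jω C_cpl),  Z_in = R_in,

with two identical skin interfaces in series (two-handed grip; a physical
symmetry assumption, since the device's internal wiring is not public). The
measured node is taken across `R_in`. Defaults `R_sc = 1 MΩ`,
`C_sc = 10 µF` make the skin contribution negligible against `R_in`, so the
chain is effectively the one-pole high-pass — which the tests exploit as a
closed-form oracle. Time-domain simulation discretizes H(s) with the
bilinear transform at the signal's sampling rate, preserving the
low-frequency pole placement at 200 Hz.

Consequences for morphology: DC and baseline are removed; every wave
acquires an opposite-sign recovery lobe with time constant `1/(2π f_c)`; at
small `C_cpl` the T-wave turns biphasic/negative and the P-wave shrinks
toward the noise floor. The R deflection stays detectable throughout the
plausible range, which is why rhythm screening survives the distortion but
P-wave-based criteria do not.

## Synthetic cohort generator

The study recordings are not public; `synthetic_ecg` generates labelled
surrogates with the study's shape: one minute, 200 Hz, single lead.

* **Template**: sum of Gaussians for P-QRS-T on a 200-point cycle grid, R
  anchored at phase 0 (beats are cut R-to-R downstream), R amplitude
  normalized to ≈1 mV before distortion. AF templates set the P amplitude
  to zero.
* **Rhythm**: NSR uses a base interval 60/HR with slow AR(1) modulation
  (coefficient of variation 0.03 — ordinary resting variability); AF draws
  i.i.d. log-normal intervals with cv 0.24 and no serial correlation
  (memoryless irregularity). RR values are clipped to 0.25–2.0 s.
* **Distortion**: the clean trace passes through the circuit model at the
  configured `C_cpl` (default 1 pF, `f_c ≈ 3.2 Hz` — a strongly high-passed
  device).
* **Device polarity**: the stored waveform is the *negated* lead. The
  emulated device wires its handles so that a correctly-held recording has
  its dominant deflections negative-going; this is precisely the regime in
  which the orientation check `mean(s) < median(s)` is decisive (margin
  3–13 % of the signal SD across heart rates, rhythms and noise levels).
  For the naturally oriented trace the statistic sits within a fraction of
  a percent of zero and would be a coin flip — an orientation test of this
  form presupposes the polarity convention, so the generator encodes it.
* **Corruption**: white noise at a configured SNR (dB, relative to the
  distorted signal power), a 50 Hz mains sinusoid (study region: Europe),
  and motion artifacts of three archetypes — baseline jump (ramped offset of
  4–8 signal SDs), broadband burst (noise at 5 SDs), rail saturation
  (clipped overdriven copy). Optional global inversion emulates a reversed
  grip.
* **Quality label**: an explicit monotone rule stands in for expert rating:
  grade 0 needs SNR ≥ 20 dB and no artifacts; SNR bands [12, 20), [5, 12),
  < 5 dB and artifact coverages ≤ 10 %, ≤ 40 %, > 40 % map to grades 1–3,
  the worse of the two deciding. Dataset generation draws grades at the
  emulated cohort prevalences (11.83 / 67.97 / 19.10 / 1.10 %) and
  synthesizes a config realizing each grade; 5 % of recordings are
  inverted, and the AF share rises with worsening grade.
* **Device decision stand-in**: the on-chip AF classifier is emulated by a
  robust RR-dispersion rule, IQR/median > 0.12 ⇒ AF (the real algorithm is
  proprietary; only its dispersion principle is public).

What the generator does **not** emulate: fibrillatory f-waves, respiration
coupling, electrode polarization noise, ectopy, or the heuristic
variability of human raters (labels follow the deterministic rule above).
Passing tests therefore demonstrate that the pipeline recovers *this*
generative structure, not that it matches clinical expert behaviour.

## Artifact detection

Non-overlapping 5 s windows (~5 beats at 60 bpm); a trailing remainder is
dropped. Two amplitude-scale-free fingerprints per window:

* **spectral**: Welch power spectral envelope of the zero-mean window
  (0.5 s Hann sub-segments, 50 % overlap, 9-bin moving-average smoothing,
  ~2 Hz resolution). The envelope, rather than the raw magnitude FFT, is
  used because the raw spectrum of a quasi-periodic ECG is a harmonic comb
  whose line positions shift with natural heart-rate drift: raw-spectrum
  correlations between clean windows fall to 0.5–0.7, while the corruption
  threshold below presupposes clean-window correlations near 1. The
  envelope is stable (clean windows ≥ 0.99) yet collapses under bursts and
  saturation.
* **amplitude**: empirical CDF evaluated on a 100-point grid spanning the
  whole recording's min–max range (shared frame across windows). This side
  catches baseline jumps, which are spectrally nearly invisible.

For window *i*, Pearson correlations to every other window are computed per
representation (self excluded), sorted descending, and the top N = 5
averaged into CC_max[i]. A window is corrupted iff either representation's
CC_max falls below 0.982 (conservative OR-fusion, maximizing artifact
recall). Both fingerprints depend only on per-window spectra/distributions,
not on beat timing, so irregular AF rhythm is not mistaken for artifact
(false-flag rate ≈ 0.1 % of windows on clean AF surrogates).

The longest run of clean windows is kept (earliest run on ties); if it is
shorter than 30 s the recording is excluded, mirroring the guideline
minimum for rhythm assessment.

## Inversion, peaks, gating

Orientation: if `mean(s) ≥ median(s)` (ties treated as inverted) the
segment is negated. Idempotent after one application on R-dominated traces.

R-peaks: Pan-Tompkins — zero-phase band-pass 5–15 Hz (3rd-order
Butterworth), derivative, squaring, 150 ms moving-window integration,
adaptive dual threshold (running signal/noise peak estimates, 0.125/0.875
updates) with a 200 ms refractory period; each detection is refined to the
local extremum of |band-passed| within ±100 ms, keeping the landing point
on the R deflection for either polarity. Sensitivity and positive
predictivity on clean surrogates exceed 99 %. Recordings whose median
instantaneous heart rate leaves 40–150 bpm are excluded as unreliable.

## Morphology and prototypes

Beats span R_i to R_{i+1} (half-open) and are linearly resampled to 200
cycle-percentage points, making averages heart-rate independent. DTW uses
the classic dynamic program with absolute-difference local cost and a
Sakoe-Chiba band of 10 % of the longer length (widened to the length
difference when necessary for feasibility; `band=1` disables the
constraint). The banded DP is verified against exhaustive monotone-path
enumeration in the tests.

Ideal prototypes come from excellent-quality normal-rhythm recordings:
their averaged morphologies are clustered into k = 4 groups by k-medoids on
the pairwise DTW matrix (10 seeded restarts; k-means proper is undefined
under DTW since the metric space has no mean — medoids keep the DTW cost,
and per-cluster pointwise averages provide the display/reference
morphologies). Clusters are then selected greedily in increasing order of
mean per-point standard deviation until their membership covers 90 % —
encoding "minimum-variance clusters covering ~90 %" as a reproducible rule
rather than a by-inspection choice.

## Features (22, fixed order)

* statistical (5): mean, median, sample SD, bias-corrected skewness, raw
  4th standardized moment (normal → 3), computed on the inversion-corrected
  valid segment; constant segments degrade to 0 with a logged warning.
* time-domain (5): mean HR (60/mean RR), SDNN (ms), coverage T_seg (s),
  mean eCDF CC_max, and the DTW distance between the averaged morphologies
  of the segment's two halves (self-consistency).
* frequency-domain (6): mean spectral CC_max; Welch band-power indices
  (4 s Hann, 50 % overlap, 0.25 Hz resolution): `bas = 1 − P(0,1)/P(0,40)`,
  `qrs = P(5,15)/P(5,40)`, `pli = 1 − P(49,51)/P(1,60)` (50 Hz mains),
  `snr = 10·log₁₀(P(5,40)/P(40,Nyquist))` dB, and the mean of the three
  indices. The exact band conventions follow the common forms of the SQI
  literature; any deviation shifts feature scales only, which the regressor
  absorbs.
* morphology (6): mean signal value at the detected R-peaks (the single
  amplitude-carrying feature), mean per-point SD of the averaged
  morphology, and Euclidean / cityblock / DTW / Pearson similarity between
  the unit-R-normalized mean morphology and the best-matching selected
  prototype (min distance, max correlation) — shape-only measures.

## Regression and evaluation

Features are standardized on training statistics (GP length-scales are
scale-sensitive across mixed units). The GP uses
`Constant × kernel + White` with isotropic length-scales; kernels: rational
quadratic, Matérn 5/2, exponential (Matérn 1/2, the usual toolbox meaning).
Hyperparameters are fit by marginal-likelihood maximization with 3 seeded
restarts; the fitted white-noise term absorbs label noise (expert grades
are subjective). Ordinal grades 0–3 are regressed as reals; predictions are
the posterior mean clipped to [0, 3]. Splits are 20 % label-stratified
holdout and 5-fold CV for validation-phase (out-of-fold) reporting.

Evaluation: RMSE, MAE, Pearson ρ (error on constant inputs); ROC of the
interpretable-vs-uninterpretable decision (positive class = grade 3,
trapezoidal AUC); balanced accuracy at the Youden-optimal threshold (the
operating point is otherwise unspecified, so the maximizer is reported
explicitly); per-subgroup ROCs trained on the identical split for
comparability; repeat-threshold curves on a 301-point uniform grid over
[0, 3]; point-biserial correlation between false device decisions and
quality scores. On synthetic data a device decision counts as false when it
contradicts the generator rhythm or was made on a grade-3 recording.

## Problem sizes and numerical choices

Test and validation runs use one-minute recordings and cohort sizes of
30–500 (2 000 scored recordings in the grade-monotonicity check); the
circuit-model simulations use 60 s of generated ECG. DTW inner loops are
numba-jitted with a pure-Python fallback. All randomness flows through
`numpy.random.default_rng` seeds; reruns are bit-identical. Welch floors
avoid division by zero on degenerate spectra; zero-variance fingerprint
windows correlate as 0 by convention (logged).

## Known limitations

* The synthetic quality label is a clean monotone function of corruption;
  real expert grades carry rater noise and non-linear heuristics, so
  real-data correlations will be lower than the surrogate recoveries.
* Artifact-heavy grade-2/3 configurations can fragment a recording below
  the 30 s rule; those recordings are excluded (reason-coded) rather than
  scored, so scored grade-3 surrogates are dominated by the low-SNR route.
* Prototype fitting assumes enough excellent normal-rhythm recordings in
  the batch; otherwise synthetic defaults are used.
* The CSV reader accepts a single channel only; multi-lead and streaming
  operation are out of scope, as is artifact repair (segments are
  discarded, never interpolated).
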