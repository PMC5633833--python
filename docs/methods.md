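# Methods

This note documents the models, defaults and numerical choices behind
`hrvseizure`, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

The pipeline assumes a single-lead ECG sampled at ≥ 128 Hz (typical
clinical rates: 256 or 512 Hz). Filtering is a zero-phase Butterworth
band-pass, implemented as an order-2 high-pass at 0.5 Hz followed by an
order-2 low-pass at 40 Hz, each applied forward-backward. The cutoffs
remove baseline wander and powerline/muscle noise while preserving QRS
energy; both are configurable.

QRS detection uses a stationary wavelet transform (db2) of the signal. The
detection function is the sum of squared detail coefficients over the
dyadic levels whose nominal bands overlap 8–32 Hz (levels 3–4 at 256 Hz,
4–5 at 512 Hz), smoothed over 50 ms. A candidate peak must exceed
`threshold_mult` (default 2.5) times the running RMS of the detection
function's magnitude (2 s window); the magnitude scale matters — an energy
signal thresholded against the RMS of the energy leaves essentially no
margin between beat peaks and threshold. Peaks closer than the 200 ms
refractory period are merged, and each detection is refined to the largest
absolute excursion of the raw signal (relative to a 0.5 s running baseline)
within ±60 ms. The record is reflect-padded by 0.5 s so beats at the record
edges remain local maxima. All constants are keyword arguments.

Degenerate inputs: records shorter than 2 s are refused; a flat line
returns an empty beat list with a warning.

## RR cleaning

An interval is flagged when it deviates from the segment mean by more than
`sd_mult`·SD (sample SD of the whole segment, default 3) **and** differs
from the previous interval by more than `rel_change` (default 30%). The
conjunction is the default; an OR mode exists because many HRV tools use
it. The first interval, having no predecessor, is judged on the dispersion
rule alone. Flags are computed once on the original series and all repairs
applied in a single pass — no iterative re-flagging — so the result is
deterministic and order-independent.

Repairs use a cubic spline over the **beat index**: the spline is fitted
through the surviving (index, RR) points and evaluated at the removed
indices. The index is the natural abscissa here because the interval end
time is itself distorted by the artifact being repaired; on the index grid
the repair is exact for locally polynomial trends (verified to 1e-6 ms for
quadratics). Beat times are left untouched.

A recording is accepted only when the corrected fraction is strictly below
2% (configurable); beyond that, interpolation biases every downstream HRV
metric.

## HRV metrics

* **SDNN, RMSSD** — sample SD (n−1) of the window's RR values; root mean
  square of successive differences. Units: ms.
* **LF, HF** — tachogram band power in 0.04–0.15 Hz and 0.15–0.40 Hz. The
  (interval-end time, RR) tachogram is mean-detrended, resampled to a
  uniform 4 Hz grid by cubic interpolation, and the one-sided Hann
  periodogram is integrated over the half-open band [f_lo, f_hi). Reported
  in absolute ms²; the total integrated power matches the resampled
  signal's variance (Parseval) to within a few percent. A window must span
  at least three cycles of the slowest band component and contain ≥ 8
  beats — this is why LF/HF use a 180 s observation window while the other
  metrics use 60 s.
* **SampEn** — Richman–Moorman template matching with m = 2 and
  r = 0.2·SD of the window, Chebyshev distance strictly below r,
  self-matches excluded, identical template counts for lengths m and m+1.
  A constant window returns 0 (perfectly regular); if no (m+1)-length
  matches exist the standalone function returns +inf, while the sliding
  pipeline caps the value at ln(#template pairs) — the largest entropy
  resolvable at that window length — to keep covariance matrices finite.
* **CSI, CVI** — from the Lorenz (Poincaré) plot of RR(n+1) vs RR(n):
  SD1 and SD2 are the dispersions across and along the identity line,
  axis lengths T = 4·SD1 and L = 4·SD2, CSI = L/T, CVI = log₁₀(L·T).
  The SD-based axis definition is deterministic (a max-extent definition
  is not, under noise); the factor 4 cancels in CSI and shifts CVI by the
  constant log₁₀16. Degenerate (constant) windows make CSI/CVI undefined;
  the feature-vector API returns NaN sentinels and the classifier pipeline
  refuses such windows upstream.

## Prediction matrices and eigen-features

At anchor time t, column j of the 7×n prediction matrix is computed from
the RR intervals ending in (t_j − Wo_metric, t_j], where the n column times
end at t and are spaced S seconds apart (defaults S = 10 s, Wp = 60 s,
n = 6; row order SDNN, RMSSD, LF, HF, SampEn, CSI, CVI). Windows are
half-open to avoid double-counting boundary beats. Construction is
strictly causal — nothing after the anchor is read — and a matrix is
refused, never padded, when history is missing: the first feasible anchor
sits max(Wo) + Wp = 240 s after the first beat.

R is the sample covariance (n−1 denominator) of the metric rows across the
n columns. The feature vector is Λ = [λ, v₁ … v₆]: the largest eigenvalue
and the first six components of the corresponding unit-norm eigenvector
(symmetric eigendecomposition). The eigenvector's sign is fixed by making
its largest-magnitude component positive; its last component is dropped,
being recoverable up to sign from the unit-norm constraint. Nothing is
normalized beyond the eigenvector itself: λ keeps its raw ms²-derived
scale, which is intentional — λ is large exactly when the HRV state is
moving, i.e. when metric rows trend within the prediction window.

## Classifier

The kernel is k(u, v) = exp(−‖u−v‖²/γ): the squared Euclidean distance is
*divided* by γ. Library conventions multiply by γ instead, so
γ_lib = 1/γ; training is delegated to libsvm (scikit-learn SVC, tol 1e-3)
with that conversion, and the decision function is re-evaluated from the
stored support vectors, dual coefficients and bias with the package's own
kernel, making serialized models (JSON) self-contained and exactly
reproducible.

Hyperparameters are chosen by leave-one-out cross-validated grid search.
The fold unit is one Λ sample, grouped by provenance so features from the
same seizure never straddle the train/test split. The C grid is
2^{−5..15}. Because the kernel divides by γ, useful γ values live on the
scale of pairwise squared distances between samples — which in turn
depends on the (unnormalized) λ units — so the default γ grid is the
median pairwise squared distance times 2^{−9..9}; fixed grids can be
passed instead. Accuracy ties are broken toward the simpler model: smaller
C first, then the smoother kernel, which under the divide-by-γ convention
is *larger* γ. The smooth-side preference matters in deployment: a
needle-thin kernel classifies far-field outliers by the sign of the bias
alone, which measurably inflates the false-positive rate on out-of-sample
interictal data. No class weighting is applied by default.

## Evaluation protocol

A *warning* is a positive classifier output at a stream anchor; a warning
*event* is a positive output whose predecessor was negative. A seizure is
detected when at least one warning falls in [onset − horizon, onset), with
horizon 300 s; a warning at exactly the onset does not count. FP/h is
warning events per monitored hour on seizure-free records — events, not
raw positive outputs, so a sustained false alarm counts once. Both
choices (event merging, half-open horizon) are flags in the API.

The leave-one-seizure-out protocol trains, for each of N seizures, on the
other N−1 preictal Λ vectors plus a pool of interictal Λ samples (default
4 per seizure) drawn at seeded random anchors from the first half of each
seizure-free record. The preictal training vector of a seizure is anchored
at the last beat at or before its onset. (C, γ) are selected once by grid
search on the full training set; each fold then retrains at those values,
scores detection on its held-out seizure record, and is applied to the
held-out interictal data — only anchors whose entire causal history lies
in the untouched second half of each seizure-free record, so training and
FP-testing periods never overlap.

## Synthetic data and the benchmark

The RR generator produces
RR(t) = m(t) + a_LF(t)·sin(2π·0.1t + φ₁) + a_HF(t)·sin(2π·0.25t + φ₂) + ε,
with ε white Gaussian jitter and phases drawn once from the seeded
generator. The carriers sit at the centers of the LF and HF bands.
Resting defaults (mean RR 800 ms; LF amplitude 30 ms, HF 25 ms, jitter
10 ms → SDNN ≈ 29 ms) are typical adult resting values. The preictal
transition ramps the LF amplitude ×2, the HF amplitude ×0.3 and the mean
RR down by 120 ms, linearly over the ramp interval — a monotone
caricature of sympathetic activation with vagal withdrawal (tachycardia,
rising CSI, falling SampEn and HF). No quantitative preictal effect sizes
exist in the literature at this granularity; these are free parameters of
the harness, documented, not physiological claims.

Ectopic beats are modelled as an early beat plus compensatory pause
(RR_i × 0.5, RR_{i+1} × 1.5), which produces both the >30% step and the
dispersion excursion the cleaning rule targets. The ECG renderer places a
Gaussian R wave (width 80 ms) flanked by smaller P and T bumps at each
beat time and adds baseline wander (~0.2 Hz), 50 Hz powerline interference
and white noise.

The bundled benchmark fixes the study conditions of the end-to-end
experiment: 12 seizure records of 17 min ending at onset, with the
autonomic ramp spanning the final 4 minutes (so the transition lies inside
the observation span of the onset-anchored matrix); plus four ~30 min
seizure-free records (≥ 2 h total). Baseline parameters (mean RR, LF/HF
depth, jitter) vary per record across physiological resting ranges so the
classifier must generalize across subjects rather than memorize one
oscillator. All record seeds derive from one master seed and stay below
2³¹. These sizes keep the full experiment under a minute on one CPU while
preserving the protocol's structure.

**What passing means.** The benchmark shows the pipeline recovers a known
preictal signature end to end — it says nothing about clinical data.
Real preictal physiology is heterogeneous, non-stationary and confounded
by movement, medication and circadian tone; real ectopy is not a single
morphology; and real ECG noise is not white. Published clinical results of
this family of methods (≈94% sensitivity, ≈0.5 FP/h) cannot be reproduced
or refuted with this harness.

## Known limitations

* The wavelet detector is single-lead and has no beat-morphology
  classification; bigeminy or atrial fibrillation would defeat the simple
  cleaning rule.
* The SD-criterion of the cleaning rule uses the whole segment's SD; very
  long segments with slow drift may under-flag (a windowed mode is the
  obvious extension).
* LF/HF are absolute powers from a Hann periodogram on a 4 Hz resampled
  grid; no Lomb–Scargle option for very irregular tachograms.
* The LOOCV grid search is O(|grid| · n²) SVM fits; fine for dozens of
  samples, not thousands.
* FP/h depends materially on the event-merging convention; per-output
  counting is available behind a flag for comparability studies.
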