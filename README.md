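# hrvseizure

Early epileptic-seizure warning from heart-rate-variability (HRV) dynamics.

Seizures perturb the autonomic nervous system minutes before their clinical
onset: sympathetic tone rises, vagal tone falls, and the beat-to-beat
structure of the RR-interval series changes in a stereotyped way. This
package implements a complete pipeline that turns a single-lead ECG (or a
pre-extracted RR series) into a streaming preictal/interictal classification
with the standard evaluation metrics of the seizure-prediction literature:
sensitivity over a 5-minute prediction horizon and false positives per hour
(FP/h). It is aimed at researchers prototyping ECG-based seizure-warning
methods who need a fully testable, reproducible reference implementation —
including synthetic data generators with known ground truth, so every stage
can be validated without access to clinical recordings.

## Method

1. **ECG front end** — zero-phase Butterworth band-pass (0.5–40 Hz, order 2),
   stationary-wavelet QRS detection with an adaptive threshold and 200 ms
   refractory period, RR-interval extraction.
2. **RR cleaning** — an interval is an artifact/ectopic beat when it deviates
   from the segment mean by more than 3·SD *and* changes by more than 30%
   versus the previous interval; flagged values are refilled by cubic-spline
   interpolation, and recordings with ≥ 2% corrections are rejected.
3. **HRV features** — seven metrics per observation window *Wo*:
   SDNN, RMSSD, LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) tachogram band power,
   sample entropy SampEn(m=2, r=0.2·SD), and the Lorenz-plot indices
   CSI = L/T and CVI = log₁₀(L·T) with L = 4·SD2, T = 4·SD1.
4. **Eigen-features** — a prediction matrix X ∈ ℝ^{p×n} stacks the p = 7
   metrics at n = Wp/S column times (defaults Wp = 60 s, S = 10 s → 7×6).
   From its sample covariance R, the classifier input is
   Λ = [λ, v₁, …, v_{p−1}]: the largest eigenvalue plus the leading
   unit-norm eigenvector. Neither the metric signals nor λ are normalized.
5. **Classifier** — soft-margin SVM with the Gaussian kernel
   k(u, v) = exp(−‖u−v‖²/γ) (note: squared distance *divided* by γ);
   (C, γ) chosen by leave-one-out cross-validated grid search with folds
   grouped by seizure.
6. **Evaluation** — streaming classification over every anchor; a seizure
   counts as detected if at least one warning falls in
   [onset − 300 s, onset); FP/h counts onsets of positive runs on
   seizure-free recordings, under a leave-one-seizure-out protocol.

## Worked example

Run the bundled demo (4 simulated seizures with a sympathetic-activation
ramp in the final 4 minutes, plus 50 minutes of seizure-free recording):

```bash
hrvseizure run --config examples/demo.yaml --out-dir demo_out
```

prints

```
sensitivity 1.000 (4/4), FP/h 0.000, CV accuracy 1.0
```

meaning all four held-out seizures produced at least one warning inside the
5-minute horizon (e.g. seizure 0 first warned 120 s before onset), no false
warnings occurred on the held-out seizure-free periods, and the grid search
separated the training features perfectly under leave-one-out
cross-validation. `demo_out/report.json` holds per-seizure detail plus the
chosen (C, γ); the RR series, onset annotations and report are plain
CSV/JSON stamped with the config hash and seed, so reruns are byte-identical.

The same stages are available piecewise (`simulate`, `extract`, `clean`,
`features`, `eigenfeat`, `train`, `evaluate`) and as a Python API:

```python
import hrvseizure as hs

rr, labels = hs.gen_rr_series(hs.RRGenConfig(duration=600, seed=42))
features = list(hs.stream_features(rr))   # one Λ every 10 s from t=240 s
print(features[0].vector)                  # [λ, v1..v6]
```

## Scope and caveats

The synthetic generators emulate the oscillatory structure HRV analysis
assumes (LF/HF modulation, ectopic beats, baseline wander, powerline
interference) and a linear-ramp preictal transition; they are a test
harness, not a physiological model. Clinical performance on patient ECGs
cannot be inferred from the synthetic benchmark — see `docs/methods.md` for
the full discussion of assumptions, parameter choices and limitations.
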