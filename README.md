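# pcgnet

Phonocardiogram (PCG) analysis for predicting exercise sudden death in
rabbits: heart-sound segmentation, cardiac-reserve features and a CNN-GRU
classifier evaluated with subject-exclusive cross-validation.

## The problem

Excessive, repeated exhaustive exercise can induce cardiac fatigue and, in
the extreme, exercise sudden death. Heart sounds carry early markers of
this decline: the first (S1) and second (S2) heart sounds delimit systole
and diastole, so their timing yields the heart rate (HR) and the ratio of
diastolic to systolic duration (D/S), a proxy for diastolic perfusion
time. This package implements a complete pipeline that classifies
short heart-sound frames from exercised New Zealand rabbits as *survival*
vs *sudden death*, and tracks the HR / D-S divergence between the two
groups across the exercise protocol's four time nodes (A: before the
protocol, through D: after the third exhaustive swimming bout). Because
the original animal recordings are not publicly available, the package
includes a first-class synthetic cohort generator with exact S1/S2
ground-truth annotations, which makes every stage independently testable.

## Method

1. **Resampling** - recordings (up to 100 kHz at acquisition) are
   polyphase-resampled to Fs = 2000 Hz; rabbit heart-sound energy lies
   below 1 kHz, which FFT/STFT inspection (Hann window, width 2048,
   overlap 1024) verifies.
2. **Envelope** - with the time scale `L_T = 0.5 * s * Fs` (minimum S1
   duration `s = 0.02` s), the characteristic envelope is the windowed
   variance

   `E(m) = (2L_T+1)^-1 * sum_{k=m-L_T}^{m+L_T} (x(k) - xbar(m))^2`,

   where `xbar(m)` is the same window's mean. The envelope is normalised
   to unit maximum, transformed by the Shannon energy
   `SE(v) = -v^2 log v^2`, smoothed with the same window and renormalised.
3. **Double-threshold S1 detection** - with `M` the mean envelope, runs
   above the low threshold `L = b * M` are candidate events; a run whose
   peak exceeds the high threshold `H = a * M` is an S1, its onset the
   run's first sample (`a = 0.8`, `b = 0.02` by default, adjustable in
   `a in [0.6, 1.1]`, `b in [0.01, 0.03]`). A second pass inside each
   inter-S1 interval locates S2, giving per-cycle systole/diastole and
   hence HR and D/S.
4. **Frames** - each S1 onset starts a 0.5 s frame (1001 samples at
   2000 Hz), standardised per frame.
5. **CNN-GRU** - frames pass through three blocks of valid-padding
   convolution (kernel 20, 9 filters, ReLU) and max pooling (pool 4,
   stride 4), shrinking 1001 -> 982 -> 245 -> 226 -> 56 -> 37 -> 9
   time steps; a 128-unit GRU (dropout 0.5) consumes the 9-step sequence
   and a 2-unit softmax head classifies. Training: Adam (lr 0.001),
   cross-entropy + L2 (0.001), batch 64, at most 50 epochs, early
   stopping after 10 non-improving validation epochs. The layers and
   their gradients are implemented in numpy (`pcgnet.nn`) and verified
   against finite differences.
6. **Evaluation** - grouped, group-stratified 5-fold cross-validation at
   the subject level (frames of one animal never straddle train and
   test), reporting Acc = (TP+TN)/(TP+TN+FP+FN), Sens = TP/(TP+FN) and
   Spec = TN/(TN+FP) with sudden death as the positive class.

## Worked example

```python
from pcgnet import (HeartCycleParams, synth_recording, detect_s1_onsets,
                    extract_cycle_features)

params = HeartCycleParams(heart_rate=234.0, ds_ratio=1.4, jitter_sd=0.005)
rec, truth = synth_recording(params, duration=5.0, fs=2000.0, snr_db=20.0,
                             rng_seed=7)
onsets = detect_s1_onsets(rec)
feats = extract_cycle_features(rec)
print(f"true HR = {truth.true_hr:.1f} bpm, true D/S = {truth.true_ds:.3f}")
print(f"detected {len(onsets)} S1 onsets (ground truth: {len(truth.s1_onsets)})")
print(f"estimated HR = {feats.hr:.1f} bpm, D/S = {feats.ds:.3f} "
      f"over {feats.n_cycles} cycles")
```

prints

```
true HR = 235.2 bpm, true D/S = 1.398
detected 20 S1 onsets (ground truth: 20)
estimated HR = 236.1 bpm, D/S = 1.366 over 18 cycles
```

i.e. all 20 S1 onsets of the 5 s recording are found, the heart rate is
recovered to within 1 bpm and the D/S ratio to within a few percent of
the realised (jittered) truth.

The full study pipeline - synthesize a default cohort (10 surviving / 11
sudden-death subjects at four time nodes), extract HR / D-S group
comparisons, and run the per-node CNN-GRU cross-validation - is one
command:

```bash
pcgnet run-all --out results_dir --seed 7
```

On the default cohort the per-node mean accuracy rises from chance at
node A (identical group distributions by construction) to near-perfect at
node D, reproducing the expected separability progression; the exact
numbers for a given seed are written to `results_dir/time_node_report.csv`.

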