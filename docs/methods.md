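# Methods

This note documents the models, parameter choices and numerical decisions
behind `pcgnet`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Signal model of the synthetic cohort

A cardiac cycle of nominal length `60 / HR` seconds (plus zero-mean
Gaussian timing jitter, default SD 5 ms) contains two bursts: S1 at the
cycle start and S2 at the end of systole, where the systolic fraction is
fixed by the D/S ratio (`systole = cycle / (1 + D/S)`). Each burst is a
Gaussian-windowed sinusoid with `sigma = duration / 6` - the simplest
morphology whose windowed variance is unimodal, which is all the
segmentation mathematics requires. Defaults: S1 150 Hz / 40 ms /
amplitude 1.0; S2 250 Hz / 30 ms / amplitude 0.2. Both carriers sit well
inside the sub-1-kHz band of rabbit heart sounds; the exact rabbit values
are unknown, so these are free parameters of the generator, not
measurements. The S2/S1 amplitude ratio of 0.2 reflects that S2 is
substantially quieter than S1 at the cardiac apex and was fixed, during
design, so that the default high threshold separates S1 from S2 lobes
with about a three-fold margin across the whole heart-rate range at
SNR 20 dB.

Recordings concatenate jittered cycles, truncate to the requested
duration, and add white Gaussian noise (parameterised either by SD or by
SNR relative to the clean signal power; cohort default SNR 20 dB) and an
optional sub-5-Hz sinusoidal baseline wander (off by default). Ground
truth carries every S1/S2 onset index plus the realised mean HR and D/S.

The default cohort is 10 surviving and 11 sudden-death subjects, each
recorded at four time nodes (A-D). Group-by-node means:

| node | survival HR | sudden-death HR | survival D/S | sudden-death D/S |
|------|------------|-----------------|--------------|------------------|
| A    | 250        | 250             | 1.50         | 1.50             |
| B    | 240        | 250             | 1.50         | 1.45             |
| C    | 230        | 256             | 1.50         | 1.35             |
| D    | 220        | 268             | 1.50         | 1.10             |

encoding: survival HR trending down (a training effect of regular
exercise), sudden-death HR exceeding survival at the later nodes,
sudden-death D/S dropping below survival at node D, identical
distributions at node A, and monotonically growing separation A -> D.
Between-subject random effects (HR SD 8 bpm, D/S SD 0.08) are shared
across a subject's nodes, which is what makes subject-exclusive
cross-validation genuinely harder than a frame shuffle. No numeric HR or
D/S reference values are available for this protocol, so the magnitudes
here are the package's own choices within rabbit physiology (180-280
bpm); only the *directions* of the group differences are anchored to the
emulated findings.

Default recording duration in the cohort is 6 s (about 20-28 cycles),
yielding roughly 200-250 frames per class per node; single recordings can
be synthesized at any duration (the emulated acquisition protocol used
5 min per animal). These problem sizes keep the full four-node experiment
around two minutes on one CPU core while leaving every statistical
contrast comfortably resolvable.

What the generator does **not** emulate: murmurs and split heart sounds,
respiratory amplitude modulation, sensor artefacts, heavy-tailed noise,
subject dropout at intermediate nodes, and within-recording
non-stationarity of HR. Passing tests on this cohort therefore establish
the correctness of the algorithms under their stated assumptions, not
field performance on real rabbit (let alone human) auscultation.

## Envelope and segmentation

The time scale is `L_T = round(0.5 * s * Fs)` with the minimum S1
duration `s = 0.02` s and `Fs = 2000` Hz, so `L_T = 20` samples. The
moving mean and the windowed-variance characteristic envelope are
computed only where the `2 L_T + 1` window fully overlaps the signal
(indices `L_T ... M - 1 - L_T`); values are kept on the original timeline
with zero-filled boundaries, so detected onsets need no offset
correction. The variance is computed as `mean(x^2) - mean(x)^2` per
window and clipped at zero against floating-point cancellation; tests
require agreement with the literal two-pass definition to 1e-10.

The Shannon-energy step scales the envelope to unit maximum, applies
`SE(v) = -v^2 ln v^2` (with `SE(0) = 0`), smooths with the same window,
and rescales to unit maximum. A z-score standardisation at the end was
considered and rejected: the double threshold multiplies the envelope
*mean*, which a zero-mean standardisation annihilates. Rescaling to unit
maximum preserves nonnegativity and a positive mean while making the
trace dimensionless. Because `SE(v) ~ v^2` for small `v` and the
variance envelope is itself quadratic in amplitude, the Shannon transform
pushes the noise floor roughly to the fourth power of the amplitude SNR -
far below the low threshold - which is why it is the default route and
required for reliable S2 timing.

Double thresholding uses `H = a * M` and `L = b * M` with `M` the mean
envelope over the valid range; defaults `a = 0.8`, `b = 0.02` are the
midpoints of the method's working ranges and can be adjusted per
recording. Runs above `L` are candidate events, kept if their peak
exceeds `H`; onsets closer than `s * Fs` samples are merged (first onset
wins). An empty result warns rather than raises, since a silent or
pathological recording is a data problem, not a programming error.
Onset placement at the low-threshold crossing systematically leads the
true burst start by up to `L_T` samples (the window reacts as soon as its
edge touches burst energy); this bias is stable (about -15 +- 8 samples
at SNR 20 dB) and within the +-`L_T` matching tolerance used throughout.

S2 onsets come from a second pass inside each inter-S1 interval: the
window opens where the S1 run has decayed below the global low threshold
and closes `s * Fs` samples before the next S1; the window is
re-thresholded against its own local mean, the first qualifying lobe is
S2 (positional identity - no interval prior, since D/S can approach 1
under exercise), and the onset is placed where the lobe first exceeds
`b` times its own peak. That last rule makes the S2 rise-detection bias
match S1's, so the shared bias cancels in systolic/diastolic durations;
without it the D/S estimate carries a several-percent systematic error.
On the raw (non-Shannon) envelope the S2 low threshold falls below the
noise floor at SNR 20 dB and most cycles are skipped; the skip count is
reported, and the Shannon route is the supported path for D/S.

Frames are `[onset, onset + 1000]` - 1001 samples, the 0.5 s window at
2000 Hz with inclusive endpoints, matching the network's declared input -
and are standardised to zero mean / unit variance individually to remove
inter-subject gain differences. Onsets whose frame would overrun the
recording are dropped.

## Classifier

The default network is the 8-layer CNN-GRU: three conv(kernel 20,
9 filters, stride 1, valid, ReLU) + maxpool(4, stride 4) blocks, a GRU
with 128 units and dropout 0.5 on its output, and a dense softmax pair.
Valid convolution gives `out = in - kernel + 1`; pooling uses floor
truncation `out = floor((in - pool) / stride) + 1`, forced by the
declared feature-map sizes (982, 245, 226, 56, 37, 9 for input 1001).
The GRU consumes the pooled output as a 9-step sequence of 9-dimensional
vectors and returns its final hidden state. Design points the
architecture description leaves open, fixed here: dropout acts on the
GRU's output (not its recurrent state); the GRU uses the classic
formulation with the reset gate applied to the previous state before the
candidate's recurrent matmul; the L2 penalty (weight 0.001, applied as
`0.5 * lambda * sum w^2`) covers weight matrices but not biases; early
stopping uses strict improvement (min-delta 0) of the validation loss
with patience 10 and restores the best-validation weights; sudden death
is the positive class; weights are Glorot-uniform (orthogonal for
recurrent matrices) under a seeded generator, and training is then fully
deterministic given the seed.

The layers, loss and Adam optimizer are implemented directly in numpy
(float32 by default, float64 available for verification); analytic
gradients of every layer are checked against central finite differences
in the test suite. The networks involved are small enough (thousands of
parameters, 9-step recurrences) that a full grouped 5-fold
cross-validation of all four time nodes runs in about two minutes on one
CPU core.

Baselines: the CNN-only model replaces the GRU with flatten + dense; the
GRU-only model feeds the raw 1001-sample frame to a GRU. Both are built
from the same declarative spec machinery, as are the ablation variants
(kernel 10/20/30, depth 4/6/8 layers, GRU units 8-256).

## Evaluation

Subjects are the unit of splitting: group-stratified round-robin
assignment into 5 test folds after a seeded shuffle, with a fraction
(default 20%, at least one subject per group) of each fold's training
subjects held out for validation-driven early stopping. Subject
exclusivity is re-verified programmatically on the materialised frame
masks of every fold. Metrics are frame-level confusion counts per fold
(sudden death positive), reported as per-fold values and fold mean +- SD;
an empty positive or negative denominator yields an explicit
undefined-metric flag rather than a silent zero. Statistical group
comparisons of HR and D/S first average recordings within subject, then
apply a two-sample t-test (Welch by default, pooled-variance optional) at
alpha = 0.05.

The per-time-node experiment segments and cross-validates each node
independently and reports the accuracy progression; on the default cohort
this is chance-level at node A (by construction) and near-perfect at
node D. The architecture-comparison harness runs any list of specs under
identical splits and seeds, reporting shape-propagation failures in the
results table instead of raising.

## Known limitations

- The segmentation assumes unimodal S1/S2 envelope lobes and fails on
  heavily split sounds or loud murmurs; thresholds may need per-recording
  adjustment outside the defaults' working range.
- The S2 detector needs the Shannon-normalised envelope; D/S from the raw
  variance envelope is unreliable at realistic noise levels.
- Onset placement carries a stable early bias below one time scale
  (`L_T`); absolute onset times should not be interpreted beyond that
  resolution.
- Frame-level accuracy treats frames as exchangeable within subject;
  subject-level aggregation is available but the default reports follow
  the frame-level convention.
- Synthetic-cohort results bound algorithmic correctness, not clinical or
  veterinary performance.
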