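# Methods

`openapco` estimates stroke volume (SV, mL per beat) from the arterial
pressure waveform with a 1-D convolutional network, trained with a
two-phase transfer protocol: pretraining on abundant labels from an
uncalibrated arterial-pressure-based cardiac output (APCO) monitor, then
tuning on scarce reference labels derived from a pulmonary artery catheter
(PAC). This note records the model, the preprocessing conventions, the
synthetic study conditions, and the numerical choices, so that every
default in the code has a stated reason.

## Signal model and preprocessing

The input is one arterial pressure channel (mmHg, nominally 500 Hz) plus
slow trend channels at 2-s cadence: APCO stroke volume (mL), PAC cardiac
output (CO, L/min) and monitor heart rate (HR, beats/min). All times are
seconds on one per-case clock with the waveform starting at 0.

Preprocessing has four steps:

1. **CO to SV.** PAC monitors report CO; targets are per-beat, so
   SV = 1000 · CO / HR (mL), using the HR tick nearest each CO tick.
2. **APCO smoothing.** APCO trends fluctuate more than physiology
   plausibly does, so they are smoothed with classic LOWESS: tri-cube
   weights, degree-1 local fit over the nearest fraction λ = 0.03 of
   points (minimum 2), no robustness iterations. A recording gap longer
   than 200 s splits the trend and each chunk is smoothed independently;
   chunks shorter than 3 points pass through. Implementation:
   `statsmodels.nonparametric.lowess` with `frac=λ, it=0`; the test suite
   checks it against a hand-coded weighted-least-squares tri-cube oracle.
3. **PAC delay.** Continuous thermodilution in trend mode lags reality by
   about two minutes; PAC-derived SV timestamps are shifted 120 s earlier
   (points shifted before case start are dropped). The lag itself is
   recoverable by `estimate_delay`, a grid search minimising the mean
   absolute difference between the shifted trend and a reference over
   nearest-neighbour-matched timestamps (±1 s), ties broken toward the
   smaller lag for determinism.
4. **Quality filtering.** The waveform is resampled 500 → 100 Hz
   (polyphase, anti-aliased; `scipy.signal.resample_poly`) and sliced into
   non-overlapping 20-s segments of exactly 2000 samples; a trailing
   partial window is dropped. Each segment is paired with the target-trend
   value nearest its *end* (within 2 s) — monitors report trailing
   estimates, and the choice is configurable since start/centre anchoring
   is equally defensible. Segments are then rejected, first failing rule
   wins, in this order: missing pressure data or target; any pressure
   sample < 25 or > 250 mmHg; target SV < 20 or > 200 mL; waveform-derived
   heart rate < 30 or > 180 beats/min (fewer than two detected beats also
   fails here); mean pulse pressure < 20 mmHg; ventricular premature beats
   (VPBs) in more than 50% of beats. Pressure is tested per raw sample;
   HR and pulse pressure as per-segment means — the per-sample/per-mean
   split is a convention this package fixes explicitly.

**Beat detection.** Threshold-free local-maxima detection: band-pass
0.5–10 Hz (2nd-order Butterworth, forward-backward), candidate maxima
above the 60th percentile of the filtered signal with a 0.33-s refractory
period (HR ≤ 180), plus a prominence floor of 0.25 × the filtered
signal's 2–98 percentile span. The prominence floor matters: during long
diastoles (HR below ~60) baseline noise otherwise produces spurious
low-amplitude "beats" that drag the segment's mean pulse pressure down.
The raw-signal systolic peak is refined within ±0.15 s of each filtered
peak and the diastolic minimum located between consecutive peaks.

**VPB surrogate.** A beat is flagged premature when its coupling interval
(time since the previous beat) and its pulse pressure *both* fall below
0.75 × the segment's 90th-percentile interval and pulse pressure. An
upper percentile, not the median, is the reference deliberately: in a
segment where most beats are premature (the very case the >50% filter
must catch) the median itself collapses onto the premature cluster and a
median-referenced rule can never fire. The 90th percentile tracks the
normal-beat envelope as long as at least ~10% of beats are normal.

## Architecture

Input: a 2000-sample pressure segment (20 s at 100 Hz) and a 4-vector of
demographics (age, sex coded male = 1/female = 0, height, weight),
z-scored with constants stored in the model bundle.

- **Stem:** two conv + batch-norm + ReLU pairs (32 channels, kernels 5
  and 3), dropout 0.5.
- **15 inception modules**, each with 4 parallel paths of 32 filters
  (6 convolution layers and 1 pooling layer per module): (a) pointwise;
  (b) conv k3 d1 → conv k3 d1; (c) conv k3 d2 → conv k3 d4 (dilated, for
  longer context); (d) stride-1 average pool (rate 2) → pointwise. Paths
  concatenate to 128 channels; temporal length is preserved inside a
  module. The exact per-path kernel/dilation assignment is configurable —
  it is an architectural stand-in satisfying the stated op budget, since
  only the budget (4 paths, 6 convs + 1 pool, 32 filters/path, concat to
  128) is pinned down.
- **Pooling schedule:** average pooling (rate 2) after each odd-numbered
  module (1, 3, 5, 7, 9, 11, 13), taking length 2000 → 15.
- **Nonlocal (global-attention) modules** immediately before modules 14
  and 15: embedded-Gaussian attention with queries/keys/values projected
  to C/2 channels, keys/values optionally pooled (rate 2), a 1/√d score
  scale, and a residual output projection that is **zero-initialised** so
  the block starts as the exact identity.
- **Regressor:** global average pooling (128) ⊕ demographics (4) → a
  132-wide concatenation → fully connected 132 → 64 → batch-norm → ReLU →
  64 → 1, dropout 0.5 on the dense layers during training.

The channel arithmetic (4 × 32 = 128; 128 + 4 = 132) is asserted at build
time and probed at run time. The default network has ~645k parameters; a
`ModelConfig.reduced()` configuration (~9k parameters: strided stem, 3
inception modules, 8 filters/path, one attention block) is the CPU-scale
workhorse of the tests. The reduced preset lowers dropout from 0.5 to
0.1: a rate tuned for a 645k-parameter network starves a 9k-parameter
one — with 0.5 the reduced model plateaus around 11–12 mL validation
RMSE, with 0.1 it reaches 6–8 mL on the same budget.

The network regresses in target-standardised units behind an output
affine (pred_mL = net · σ_target + μ_target, constants fitted on the
training split and stored in the bundle). Without this, a freshly
initialised head must traverse ~80 mL at adaptive-step pace, which
dominates early training for no benefit.

### Numerical core

The layers run on a small in-package reverse-mode autodiff over numpy
(float32 by default, switchable to float64): broadcast arithmetic,
batched matmul, ReLU, reductions, concatenation, shift-stabilised
softmax, and strided/dilated 1-D convolution and average pooling built on
copy-free sliding-window views with slice-based scatter adjoints.
Gradient correctness is pinned by central-difference checks at 1e-6
relative tolerance in float64.

## Training protocol

Loss: root-mean-squared error over the batch. Optimiser: RAdam (β =
0.9/0.999) wrapped in Lookahead (sync period 5, α = 0.5); lr0 = 1e-3 —
lr0 and the Lookahead constants are conventional defaults, recorded in
`TrainConfig`. Batch size defaults to 512 (tests use 32 at reduced
scale). Every 200 steps (50 at reduced scale) the model is validated on a
30% split grouped by case — all segments of one patient stay on one side,
since overlapping intraoperative segments would otherwise leak. When the
validation RMSE has not reached a new minimum for `patience` consecutive
validations (default 50; small in tests), the best weights are restored
and training restarts with the learning rate halved; after `max_restarts`
(default 3, i.e. a final lr of lr0/8) the next exhaustion stops training.
The returned model is always the best-validation state; a final
validation runs when training ends between checkpoints so late progress
counts.

Transfer: `pretrain` fits a fresh model on APCO-labelled samples;
`tune` re-initialises the regressor (both dense layers Xavier, batch-norm
reset) and retrains on PAC-labelled samples with *all* parameters
trainable — the conservative reading of "the parameters were tuned";
`freeze_extractor` is available as a config switch.

## Synthetic study conditions

The simulator exists so that every pipeline stage is testable against
exact ground truth; realism beyond that is a non-goal.

- **Waveform:** built beat by beat — diastolic baseline + a raised-cosine
  systolic bump (width 0.30 s) + a dicrotic bump (12% amplitude, 0.30 s
  delay — deliberately inside the detector's 0.33-s refractory period) —
  with per-beat pulse pressure = 0.5 mmHg/mL × that beat's true SV and
  diastolic pressure = MAP − PP/3. Additive Gaussian noise, 1 mmHg.
  A Windkessel mode could be added later; the raised-cosine construction
  is what makes the SV↔morphology link exact and invertible.
- **Trajectories:** HR ~ U(55, 95) beats/min, SV ~ U(50, 100) mL at case
  start, per-beat random walks (SV step 0.4 mL, ~10 mL drift over 10
  min) clipped to 48–145 mL so pulse pressure stays above the 20-mmHg
  filter in clean data; MAP ~ U(80, 100) mmHg.
- **APCO channel:** true SV at 2-s ticks × gain 0.85 + 12 mL offset +
  N(0, 8 mL) fluctuation. The gain/offset is the device discrepancy the
  transfer step must overcome; the 8-mL fluctuation is what LOWESS
  smoothing exists to remove.
- **PAC channel:** CO = SV·HR/1000 at 2-s ticks, trailing moving average
  over 60 s, timestamps shifted 120 s later — the trend-mode behaviour
  the delay shift undoes.
- **Artifacts** are built to trip exactly one filter each: hypotension
  clip (→ pressure range), flatline (→ HR range via zero beats), pulse-
  pressure compression, VPB burst (two of three beats early and
  under-filled, resynthesised at an SV floor of 70 mL so the mean-pulse-
  pressure rule does not fire first), and a device-side SV outlier that
  corrupts trend ticks directly. Corpus generation aligns artifact
  windows to 20-s segment boundaries, which makes rejection closure exact
  (the rejected set equals the recorded corrupted set, reason for
  reason). The SV outlier is assigned to PAC-role cases only: on an
  APCO-role case the LOWESS step would blur a label outlier into
  neighbouring targets and exact bookkeeping is impossible by
  construction.

What passing tests therefore show: the pipeline recovers exactly the
information the simulator encodes (amplitude-coded SV, known delays,
known corruption). What they do not show: performance on real arterial
waveforms, whose SV information is not a clean amplitude code and whose
artifacts are not segment-aligned. The package's clinical claims are
limited to faithfully implementing the method; validating it on patients
requires registry data.

## Desk-scale study sizes

The training-dependent tests and the acceptance script use: 18 APCO-role
cases (~540 samples) for pretraining; a fresh 6-case APCO-role corpus as
the pretraining hold-out (evaluating on fresh cases rather than the
validation split keeps the target spread representative — a 30% split of
18 cases can by chance cluster within a few mL of each other, which makes
any spread-relative metric meaningless); 10 PAC-role cases × 10 samples
for tuning; 6 held-out PAC-role cases for testing; the reduced
architecture; 700 pretraining and 500 tuning steps at batch 32. These
sizes were chosen once as the smallest study in which the pretraining
model clearly beats the mean predictor (held-out MAE under 0.6 × target
SD), its predictions correlate with true SV at r > 0.9, and tuning beats
from-scratch training on the same 100 PAC samples (median over 5 seeds). With only 7 training
cases behind it, the tuned model does *not* beat the untouched pretrained
model at this scale — recovering a freshly initialised head from 100
samples costs more than the domain-shift correction gains; the transfer
claim is strictly tuned-vs-scratch, which is the paired design the
protocol presumes.

## Numerical choices and degenerate inputs

- Ties in `estimate_delay` go to the smaller lag; lags with no
  overlapping support are excluded and an all-excluded grid is an error.
- Percentage metrics exclude zero-reference points and report the count;
  Spearman of a constant series is NaN; a 4-quadrant analysis with every
  pair inside the 10% exclusion zone is flagged undefined, never 0%.
- The exclusion zone applies to both axes (pair dropped if either change
  is inside 10%), the common 4-quadrant convention; a reference-axis-only
  switch exists.
- Limits of agreement are bias ± 1.96 SD of the paired differences; each
  limit's 95% CI uses the classic large-sample standard error
  1.96 · SD · √(3/n).
- Paired error comparison with zero-variance differences reports p = 1
  (all-zero) or the floating-point tiny (constant nonzero shift) instead
  of dividing by zero.
- Batch norm: eps 1e-5, momentum 0.1; conv weights He-initialised, dense
  Xavier; all seeded through `numpy.random.default_rng`.

## Known limitations

- The tuned-vs-scratch margin at n = 100 tuning samples is real but
  modest (a few mL of RMSE, consistent across seeds); single-seed
  comparisons can be close.
- The beat detector is built for the simulator's morphology family and
  ordinary arterial waveforms; heavily damped traces, intra-aortic
  balloon pumps or severe arrhythmia are out of scope.
- The full 645k-parameter network is instantiable and probe-tested on
  CPU but not trained in the test suite; training it is a GPU-scale
  undertaking.
- Case bundles store the waveform as delimited text; at hours-long
  recordings this is bulky, and a binary container would be the next
  step.
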