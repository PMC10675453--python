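# Methods

## Problem and scope

`cowave` estimates cardiac output (CO, L/min) from two simultaneously
recorded waveforms: a photoplethysmogram (PPG, arbitrary units) and an
invasive arterial-pressure waveform (ART, mmHg), both sampled at 500 Hz,
with reference CO readings available every 2 s. The package implements the
complete estimation pipeline — waveform simulation with a known ground
truth, band-pass preprocessing, windowed segmentation, a seven-rule segment
quality screen, a dual-channel 1-D U-Net regressor with bidirectional LSTM
layers, and a method-comparison statistics suite (Bland–Altman bias and
limits of agreement, RMSE, RMSNE, percentage error, Pearson r).

## Synthetic data model

Real paired PPG/ART/CO recordings come from clinical databases that cannot
ship with a package. The simulator therefore generates records with enough
physiological *structure* for every downstream stage to be exercised and
validated, without attempting biophysical fidelity (no pulse-wave
propagation or Windkessel dynamics).

Each case is built from a constant heart rate HR (beats/min), respiratory
rate (default 15 cycles/min, i.e. 0.25 Hz), systolic/diastolic pressures,
and a PPG baseline/amplitude placing the PPG in the 20–80 a.u. band. Beat
templates are phase-locked to the cardiac cycle:

- **PPG**: a two-Gaussian pulse (systolic peak at 28% of the cycle, dicrotic
  bump at 62%), normalized to [0, 1] and scaled by the configured amplitude.
- **ART**: a raised-cosine systolic upstroke followed by an exponential
  diastolic decay, continuous across beat boundaries, spanning the
  diastolic-to-systolic pressure range.

Additive respiratory sinusoids (3 a.u. on PPG, 2 mmHg on ART) and white
noise (SD 0.5 per channel) complete the signals. The magnitude spectrum of
a clean PPG channel shows local maxima at the configured cardiac and
respiratory frequencies.

**Ground-truth law.** Every record obeys

    CO = HR × SV / 1000,    SV = a + b·PP,

with PP the configured pulse pressure and defaults a = −10 mL,
b = 1.6 mL/mmHg (chosen so that physiologic PP values of 30–90 mmHg map to
stroke volumes of roughly 40–135 mL). Reference CO readings add N(0, 0.1)
L/min measurement noise and are truncated to the physiologic band
[2, 10] L/min.

**Morphology encodes stroke volume.** Model inputs are min-max normalized
per segment and channel, which deliberately erases absolute amplitude — so a
network could never read PP off the normalized ART trace directly. The
simulator therefore encodes SV in the ART beat *shape*: the systolic
time-to-peak fraction (0.12 + 0.0012·SV of the cycle) and the diastolic
decay fraction (0.15 + 0.0025·SV) both grow with SV. The PPG shape is
SV-independent by construction. Consequently a PPG-only model can recover
heart rate but not stroke volume, while the dual-channel model sees both —
the synthetic analogue of the empirical finding that the two channels carry
complementary information.

**Population prior.** Multi-case datasets draw case-level CO from a normal
distribution with mean 5.01 and SD 1.60 L/min truncated to [2, 10]; pulse
pressure is drawn around an affine function of the CO target (keeping heart
rate in a 38–135 beats/min band), diastolic pressure independently
(N(68, 7²) mmHg clipped to [50, 95]), and HR is solved from the ground-truth
law so the realized CO equals the target.

**CO alignment convention.** Each CO reading summarizes one 2 s interval
and is aligned to the sample at the *center* of that interval
(sample (k + ½)·co_interval·fs). This keeps every reading's index inside
the record, preserves exact inter-reading spacing, and gives a 60 s record
30 readings of which exactly 28 have the full ±1024 samples of context
needed for a segment. How real acquisition systems align CO timestamps to
waveform samples is vendor-specific; anyone adding a real-data loader must
re-examine this convention.

**What the simulator does not emulate**: beat-to-beat variability
(HR and SV are constant within a case), arrhythmias, baseline wander beyond
the respiratory sinusoid, sensor-specific PPG morphology changes, motion
artifacts other than the targeted injected kinds, and any dependence of
beat shape on heart rate. Passing tests therefore demonstrate that the
pipeline recovers a *known, learnable* waveform→CO relationship under
controlled conditions — not that the model would reach any particular
accuracy on clinical recordings.

## Preprocessing

- **Filtering**: second-order Butterworth band-pass, 0.5–10 Hz, applied
  forward–backward (zero-phase) by default so PPG/ART morphology stays
  aligned; a causal mode is available (`FilterConfig(zero_phase=False)`).
  Zero-phase application squares the magnitude response; at 2 Hz the gain
  remains within 5% of unity, at 50 Hz below 0.2%.
- **Middle window**: the centered 60 s of each record is analyzed; shorter
  records and records with undefined samples inside the window are excluded
  (with a logged reason).
- **Segmentation**: one candidate segment per CO reading, spanning the
  half-open window [c − 1024, c + 1024) around the reading's sample c
  (4.096 s at 500 Hz, and a multiple of 16 as the four pooling stages
  require). Candidates crossing either record end are dropped and counted.
- **Normalization**: quality control runs on the *raw* windows (the 0.5 Hz
  high-pass removes the DC level that the absolute amplitude thresholds
  refer to); the filtered windows are then min-max scaled to [0, 1] per
  segment per channel. Labels are scaled by the *fixed* physiologic map
  (CO − 2)/8 rather than a dataset min-max, so the inverse map is
  data-independent and saved models are portable across datasets.

## Quality screening

Eight boolean rules per segment (seven waveform/label screens plus a
completeness check): CO label in [2, 10] L/min; every raw ART sample in
[30, 200] mmHg; every raw PPG sample in [10, 100] a.u.; ART peak-to-peak
≥ 30 mmHg; PPG peak-to-peak ≥ 20 a.u.; max absolute adjacent-sample
difference ≤ 20 a.u. (PPG) and ≤ 30 mmHg (ART); no undefined samples.

Design choices: amplitude rules check *every* sample (an extrema-only
reading would make the separate peak-to-peak rules redundant); slew rules
use absolute differences, catching both polarities; a segment failing
several rules counts once in the failure total but in each rule's tally, so
failure attribution stays honest. NaN samples fail only the completeness
rule — the other rules are evaluated on the finite samples — keeping
artifact attribution targeted.

## Model

A 1-D U-Net adapted for sequence regression:

- **Encoder** (default 4 levels): Conv1d(kernel 3, same padding) + ReLU,
  then max-pool by 2; channel counts double per level from 16.
  One convolution per level keeps the CPU cost proportionate to the small
  model widths used here.
- **Bottleneck**: a channel-doubling convolution followed by two
  bidirectional LSTM layers (64 units per direction) over the
  length-128 bottleneck sequence.
- **Decoder**: per level, nearest-neighbour upsampling ×2 + convolution,
  concatenation with the matching encoder feature map (skip connection),
  and a merging convolution back to the mirrored channel count.
- **Head**: a bidirectional LSTM over the full-resolution decoder output;
  its final forward and backward states (concatenated) feed a single fully
  connected unit. Flattening the whole output sequence into a dense layer
  was rejected as parameter-explosive; the recurrent summary keeps the head
  size independent of input length.

The input length must be divisible by pool_factor^depth (16 by default);
this is validated at construction. All initialization is seeded
(Glorot-uniform); LSTM forget gates start at 1.

The network, including the reverse-mode differentiation it trains with, is
implemented in-package on numpy; gradients of every primitive and of the
assembled network are verified against central finite differences in the
test suite.

**Training protocol**: MSE loss, MAE metric, Adam at learning rate 0.001,
batch size 32, 500 epochs (defaults). The dataset is split 80/20 at segment
level (case-level splitting is available and documented: segment-level
splitting lets segments of one case appear on both sides, which inflates
apparent performance; it is nonetheless the default to match the protocol
this package replicates). 10% of the training set (rounded) is held out for
validation; the checkpoint with the smallest validation loss is returned.
By default the validation subset is fixed across epochs — resampling it
every epoch (`val_mode="per_epoch_resample"`) reproduces the noisier
original protocol but makes "best validation epoch" less meaningful.

## Evaluation

For paired predicted/reference CO sequences, differences are
d = y_pred − y_ref and:

- bias = mean(d) (signed; a printed formula squaring the difference inside
  the bias cannot yield the negative biases reported for this method family
  and is treated as a typo),
- std = population (1/n) SD of d; LOA half-width = 1.96·std;
  limits of agreement = bias ± 1.96·std,
- RMSE = √MSE; RMSNE = 100·RMSE/mean(y_ref) %;
  PE = 100·1.96·std/mean(y_ref) % with PE < 30% the conventional
  clinical-acceptability criterion (the denominator is the mean reference
  CO of the evaluated pairs),
- Pearson r; on constant input it is reported as NaN with an explanatory
  note rather than a silent 0,
- the identity-line check is an ordinary least-squares fit of y_pred on
  y_ref (slope 1, intercept 0 under perfect agreement).

Every statistic is cross-checked against a naive loop implementation on
random pair sets, and the suite's operating-point checks confirm the
internal consistency of the published metric values this implementation is
benchmarked against (√0.254 = 0.504; 1.96 × 0.502 = 0.984;
−0.04 ± 0.984 → [−1.024, 0.944]).

## Reduced-scale study conditions

Tests and the acceptance script shrink the *problem size*, never the study
conditions: 64 Hz sampling with 2 s / 128-sample windows (the same ~2–4
beats per window as 2048 samples at 500 Hz), ~120 cases ≈ 1,300 candidate
segments, a narrow model (depth 3, 8 base filters, 16 LSTM units), 25
epochs. At this scale the held-out Pearson r against the simulator's
ground-truth CO exceeds 0.8, and the dual-channel model's held-out MSE is
at or below the PPG-only model's on the same split — the reduced-scale
analogues of the full-scale dual-channel findings.

## Numerical choices and degenerate inputs

- Filtering rejects non-finite input explicitly, pointing to the
  missing-value screen; cut-offs at or above Nyquist are validation errors.
- Normalization of a zero peak-to-peak channel is an error naming the
  channel (such segments should have been screened).
- Splitting uses `floor(train_fraction · n)` for the train size; the
  validation share uses `round` (10% of 7,556 → 756).
- `best_epoch` is 1-based; ties in validation loss keep the earlier epoch.
- All randomness flows from explicit integer seeds; one global pipeline
  seed fans out to per-stage seeds via a seed sequence, so identical seeds
  give bit-identical simulations and byte-identical agreement reports.

## Known limitations

- The simulator's waveform→CO law is imposed, not physiological; recovery
  results quantify pipeline correctness, not clinical accuracy.
- Exact layer widths of the original architecture are not recoverable from
  its description; the defaults here are declared, not claimed identical.
- The numpy network trains on one CPU at desk scale only; the default
  2048-sample/500-epoch configuration is API-complete but sized for GPU
  frameworks, not for this engine.
- No repeated-measures correction is applied in the Bland–Altman analysis
  (segments of one case are treated as independent), and no confidence
  intervals are reported for the limits of agreement.
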