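# Methods

`emgrec` implements a real-time myoelectric motion-intent recognition
pipeline for six upper-limb rehabilitation motions — elbow flexion/extension
(EF/EE), shoulder flexion/extension (SF/SE) and their compounds (ESF/ESE) —
decoded from three surface-EMG channels (biceps brachii, triceps brachii,
anterior deltoid). This note documents the models, the synthetic data the
package is exercised on, the numerical choices, and what the shipped tests do
and do not demonstrate.

## Signal model of the synthetic generator

No public recordings exist for this protocol, so the package ships a
generator (`emgrec.synth`) whose defaults *are* the study conditions the rest
of the pipeline assumes: 20 kHz acquisition, 2 s trials, 50 repetitions of
each of the six motions per session (300 trials), a stratified 70/30
train/test split, plus one rest and one contraction calibration segment per
session.

Each trial channel is

    x(t) = e(t) · g[m,c] · j · n_band(t) + a_mains sin(2π·50t + φ)
           + a_drift sin(2π f_drift t + ψ) + σ w(t)

- `n_band` — unit-RMS Gaussian noise band-limited to 20–450 Hz, the standard
  surrogate for the interference pattern of many asynchronous motor-unit
  action potentials. The band-limiting filter is a sharp 2049-tap
  linear-phase FIR so that ≥95% of a trial's periodogram power stays inside
  the physiological band even after envelope modulation (a property the
  spectral tests assert).
- `e(t)` — raised-cosine rise–hold–fall envelope with 0.25 s ramps: the
  motion is performed once, smoothly, within the trial.
- `g[m,c]` — the 6×3 activation-gain matrix. Rows encode the muscle-synergy
  structure of the motions: EF is biceps-dominant, EE triceps-dominant,
  SF/SE deltoid-dominant (SE, the concentric lift, stronger than SF), and
  the compound rows are the sums of their constituent single-joint rows
  (ESF = EF + SF, ESE = EE + SE). Compounds therefore correlate with their
  constituents, which is what makes them the hardest pairs to separate —
  the same confusion structure one expects from real compound motions.
- `j` — lognormal per-trial, per-channel gain jitter (σ = 0.15). Subjects
  contract at a comfortable 30–40% of maximum voluntary contraction, so
  repetition-to-repetition amplitude varies on the order of ±15%; without
  jitter the classification problem is unrealistically easy.
- mains (50 Hz, amplitude 0.10), baseline drift (0.5 Hz, amplitude 0.05)
  and white sensor noise (σ = 0.02) are the interference terms the
  preprocessing chain exists to remove. Units are normalized mV-scale; only
  ratios matter after amplitude normalization.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical (motion, params, seed) reproduce a
trial bit-for-bit.

**What the generator does not model:** motor-unit-level physiology
(recruitment, firing statistics, MUAP shapes), electrode shift, fatigue,
inter-subject variability, and crosstalk dynamics beyond static gain
mixing. Consequently, passing benchmarks here demonstrate that the pipeline
is implemented correctly and can learn amplitude-pattern-coded motions end
to end — they are not evidence about accuracy on human recordings, whose
discriminative information is richer but far noisier.

## Preprocessing

Four causal stages (`emgrec.preprocess`), in fixed order:

1. **Downsample** 20 kHz → 1 kHz: 8th-order Butterworth anti-alias low-pass
   at 0.45 × 1 kHz, then decimation (integer ratios only).
2. **Notch**: second-order IIR at 50 Hz, Q = 30, against mains interference.
3. **Band-pass**: 4th-order Butterworth, 20–450 Hz, the physiological sEMG
   band. 450 Hz sits at 0.9 Nyquist; the anti-alias filter upstream guards
   the top edge.
4. **Normalize**: each channel divided by its calibration max-abs and
   clipped to [−1, 1]. The reference is the pre-collection *contraction*
   calibration (one nominal-gain trial per motion, concatenated);
   per-window max-abs normalization is available as an alternative mode.

All filters run as causal SOS (`scipy.signal.sosfilt`) — never zero-phase —
because the target is a streaming loop with a hard latency budget where
output at time t may depend only on input up to t. Filter state persists
across chunks in `StreamingPreprocessor`, so chunked streaming is
bit-identical to batch processing (asserted by tests at several chunk
sizes).

## Windowing and the motion trigger

Signals are segmented into 192 ms analysis windows advanced by 15 ms
(192/15 samples at 1 kHz; one window = 192 × 3 = 576 points). Per channel,
the trigger threshold is 75% of the mean per-window MAV of the contraction
calibration; a window containing motion intent is one where *any* channel's
MAV exceeds its threshold (the most sensitive combination rule — the
per-channel rule composition is otherwise arbitrary). The triggering window
and the next two form a **burst**, the unit of one classification decision;
its acquisition span is 192 + 15 + 15 = 222 ms.

Two refractory policies are provided:

- `retrigger="immediate"` (default): scanning resumes right after a burst's
  last window. Under this rule burst count is monotone in signal amplitude.
- `retrigger="rearm"`: after a burst the trigger must see an all-channel
  sub-threshold window before firing again, so one sustained contraction
  yields exactly one decision — the accounting used for per-motion accuracy
  and by the streaming control demo.

The streaming trigger reproduces the batch burst sequence exactly for any
chunking (tested in both modes).

## Features and SVM baselines

Per window and channel: MAV, RMS, waveform length, zero crossings, slope
sign changes, and 4th-order autoregressive coefficients. ZC/SSC use a 0.01
(normalized units) amplitude deadzone; without one, sensor noise dominates
both counts. AR coefficients are estimated by the Burg method
(`statsmodels.regression.linear_model.burg`), the standard estimator for
short EMG windows — stable and lower-variance than Yule–Walker at n = 192.

Three feature-set variants (channel-major layout): SVM1 = [AR(4), RMS, WL,
ZC] (21 values), SVM2 = [MAV, ZC, WL, SSC] (12), SVM3 = [RMS, MAV, AR(4),
WL] (21). `EmgSvmClassifier` standardizes features and fits an RBF SVC
(C = 1, gamma = "scale", one-vs-one) — reasonable defaults, deliberately
untuned, since the SVM is the comparison baseline rather than the
contribution. Burst decisions use the same 3-window majority vote as the
CNN.

## The lightweight CNN

`LwCNNClassifier` treats the normalized 192 × 3 window as a one-channel
image (no spectrogram transform). Topology: two blocks of
conv(16, 3×3, stride 1, same) → pool → conv(32, 3×3, same) → pool, with
2 × 2 "same" max pooling after *every* convolution (four conv layers
total), then flatten (12 × 1 × 32 = 384) → FC(512) → dropout 0.5 → FC(6) →
softmax. Every conv/FC layer carries batch normalization (conv → BN → ReLU;
inference uses running statistics, momentum 0.9).

The defaults use **215,478** trainable parameters (conv: k²·c_in·c_out +
c_out; BN: 2c; FC: d_in·d_out + d_out), inside the 367 k budget that keeps
the model deployable on embedded real-time hardware; `strict_budget` makes
an over-budget configuration an error instead of a warning. FC widths are
otherwise unconstrained design choices; 512 leaves comfortable margin.

The network is implemented in pure numpy (`emgrec._nn`): im2col convolution,
max-pool with stored argmaxes, Adam (lr 1e−3, β = 0.9/0.999), batch size 32,
up to 30 epochs with early stopping (patience 5 on a 10% validation split of
the training windows). Training is deterministic for a fixed seed under
single-threaded BLAS; tests assert identical loss curves across repeated
runs. A deep-learning framework is deliberately not required: the model is
small enough that a self-contained implementation is simpler to audit and
to ship.

Burst fusion: plurality vote over the three per-window argmaxes; ties
(including three distinct argmaxes) are broken by the highest summed
probability among the tied classes. The vote is exhaustively tested against
a brute-force oracle over all 6³ argmax combinations.

## Evaluation statistics

Confusion matrices (rows = truth), per-class precision/recall/F1 with the
0/0 → 0 convention (degenerate classes are flagged), overall accuracy at
burst granularity (one decision per motion execution). ANOVA helpers
implement the classical balanced fixed-effects decomposition — one-way, and
two-way with interaction for the 2 classifiers × 2 testing modes × subjects
layout — reporting F, p, η² = SS/SS_total and ω² = (SS − df·MS_err)/
(SS_total + MS_err). Unbalanced two-way designs are rejected rather than
silently approximated; η² ≥ ω² and exact SS additivity are property-tested,
and results are cross-checked against statsmodels.

## Real-time loop and latency budget

`stream_decide` replays a raw signal in chunks (default 15 ms) through the
stateful preprocessor and trigger; each burst is classified and becomes a
`DecisionEvent` with a latency ledger: acquisition (222 ms from the window
geometry), inference (wall-clock, measured), command transmission
(configurable, default 6 ms — mid-range of a 5–8 ms UART link) and arm
response (10 ms, from the arm's datasheet). The 300 ms budget is flagged,
never enforced; with worst-case components (29, 8, 10) the total is 269 ms.
Inference time is measured only to fill the ledger — no test or acceptance
result depends on hardware timing.

The simulated arm has two binary joints. Command targets: EF/EE set the
elbow flexed/initial, SE/SF set the shoulder lifted/initial, ESF targets
(flexed, lifted), ESE returns both joints to initial — the
flexion/extension pairing symmetry of the compound motions. A command whose
target posture is already held is `skipped_redundant` (state unchanged) and
excluded from control-accuracy tallies; the 24-entry transition table is
exhaustively tested.

## Problem sizes and numerical choices

- The shipped benchmark uses the full default session (300 trials), 8
  training windows per trial drawn evenly from each trial's supra-threshold
  region (≈1,680 training windows), and one first-burst decision per test
  trial (90 decisions). These sizes make the benchmark reproducible on a
  single CPU in a few minutes while exercising the complete protocol.
- If a test trial never crosses threshold, the three windows centred on its
  MAV peak stand in, so every trial contributes exactly one decision.
- Trigger thresholds and normalization come only from the calibration
  segments, never from the trials.
- Degenerate inputs are errors, not NaNs: zero-variance windows for AR,
  single-class training sets, zero calibration amplitudes, non-integer
  decimation ratios.

## Known limitations

- Synthetic motions are coded almost entirely in per-channel amplitude;
  spectral and temporal structure carries little class information, so the
  CNN's margin over the feature-based SVM is smaller here than one would
  expect on real recordings.
- The two-way ANOVA handles balanced designs only.
- The streaming loop models computation and transmission delays as ledger
  entries; it does not emulate the acquisition hardware or the robot
  protocol.
- 450 Hz is 0.9 × Nyquist at the 1 kHz processing rate, so the band-pass
  upper skirt is partly shaped by the decimation anti-alias filter.
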