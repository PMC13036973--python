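# Methods

## Problem setting

The package detects imminent ankle-injury risk from a 200 Hz stream of
ankle-mounted IMU data (tri-axial accelerometer + gyroscope; magnetometer
and bilateral mounts are configuration switches).  The stream is cut into
200 ms windows with 50 % overlap (40 samples × 6 channels at the default
configuration); each window is classified risk / no-risk, and a parallel
forecasting path predicts motion features 150 ms ahead to raise alerts
*before* the event.  The target regime is a microcontroller-class wearable,
so the ensemble's size is itself a control variable.

## Signal conditioning

Fixed order: per-channel bias/scale calibration → fourth-order zero-phase
Butterworth low-pass at 20 Hz (acceleration and gyroscope channels only)
→ complementary-filter gravity removal → resampling to the common 200 Hz
grid → windowing → z-normalization with training-split statistics.

The complementary filter propagates the unit gravity direction with the
gyroscope rates (rotating-frame transport ġ = −ω × g) and nudges it toward
the normalized accelerometer vector with per-step weight 0.02 (i.e.,
0.98 gyro / 0.02 accel).  The blend weight is a design default — small
enough that transient linear accelerations do not corrupt the attitude,
large enough to bound gyro drift within a session.  Dead accelerometer
samples (zero norm) fall back to the gyro-only update.

Windows overlapping the 200 ms pre-injury segment by at least half a
window, and starting no earlier than that segment, are labeled risk; with
50 % overlap this labels exactly the two windows whose content is
dominated by pre-event kinematics.  Training-split imbalance (~1:15) is
addressed by SMOTE on the flattened 240-dimensional window vectors
(k = 5 minority neighbors, oversampled to parity) plus class weights
inversely proportional to post-SMOTE frequencies; validation and test
splits are never resampled, and normalization statistics carry a split tag
so that test-set leakage is structurally impossible.  Splits are at the
subject level, 70 / 11.5 / 18.5 %.

Samples inside sensor-dropout intervals are flagged in an explicit
validity mask (not zero-filled at generation time) so the conditioning
chain can choose its policy: filters bridge gaps by linear interpolation
and re-flag them, and dropout samples are zero-imputed only after
normalization, with the mask retained as window metadata.  A window with
every channel missing forces the CNN-only fallback (α = 1) at runtime.

## Ensemble branches

**CNN.** Three depthwise-separable convolution blocks, kernel sizes 5/3/3,
channels 32 → 64 → 128, stride 2 each (temporal trace 40 → 20 → 10 → 5),
batch norm + ReLU, global temporal average pooling, linear projection to
two logits.  The block applies the pointwise (1×1) stage *before* the
depthwise stage by default — the order the fused-block equation
prescribes — with `conv_order="conventional"` available to restore the
usual factorization; the two orders differ only in which channel space the
depthwise filter acts on.  Global average pooling was chosen over last-step
readout because the 5-step final feature map is short and impacts can fall
anywhere in the window.

**Quantization.** Post-training, symmetric, per-tensor int8 for weights
([−127, 127], scale = max|x|/127); activations use per-layer scales
calibrated on a held-out batch; batch norm is folded into the final conv
stage of each block on the quantized path.  Arithmetic is simulated
quantization (float compute on int8-gridded values), which reproduces the
rounding behavior of int8 inference without hardware kernels.  The
round-trip bound |x − deq(q(x))| ≤ scale/2 is enforced by construction and
property-tested.

**LSTM.** Two stacked layers (64, then 32 hidden units), gate order
i/f/g/o with forget-gate bias 1, dropout 0.2 between layers at training
time only, last-step readout of the 32-dim hidden state to two logits.
Magnitude-based unstructured pruning zeroes the ⌊ratio·n⌋
smallest-magnitude entries of each input and recurrent matrix (biases and
the readout exempt); masks are kept separate from the dense weights, so
the runtime can re-prune from the dense checkpoint at any ratio —
β changes are reversible.  Ties in |w| break by stable flat index.  The
training-time default ratio is 0.4, followed by a brief fine-tune under
the mask.

**Training.** Both branches minimize weighted softmax cross-entropy with
Adam, early-stopping on validation loss; single-threaded numpy makes runs
bit-reproducible from the seed.  Hand-written backprop is verified against
central finite differences to ~1e−8 relative error in the test suite.

## Gaussian-process forecaster

A scalar GP over time per feature dimension with composite kernel

    k(t_i, t_j) = σ_f² (1 + √3 d/ℓ_m) exp(−√3 d/ℓ_m)
                + σ_p² exp(−2 sin²(π d / T) / ℓ_p²),   d = |t_i − t_j|.

Defaults: σ_f² = 1.24, σ_p² = 0.58 (the framework's validated variances),
ℓ_m = 0.5 s, ℓ_p = 0.3, period T = 0.7 s (≈ one stride at 1.4 Hz cadence),
observation noise 0.05.  The unprinted length scales are design defaults
chosen at gait time scales and are refittable: `fit_hyperparameters`
maximizes the exact log marginal likelihood in log-parameter space with
L-BFGS-B and five seeded restarts.

The forecast target is a per-window summary vector (per-channel RMS plus
peak gyro magnitude, 7 dimensions), each dimension modeled independently;
the observation window holds the 50 most recent vectors, so the
covariance factorization is bounded at 50 × 50 regardless of stream
length.  Cholesky jitter escalates 1e−8 → 1e−4 (×10 steps) before
failing.  The posterior at t_last + 150 ms feeds a logistic risk head
r = sigmoid(wᵀx̂ + b), fitted by L2-regularized logistic regression on the
SMOTE-rebalanced training features — rebalancing keeps the head calibrated
enough to cross the fixed alert threshold τ = 0.6 despite the 1:15 class
imbalance.  An alert is raised when r > τ or the fused classifier votes
risk; both pathways feed the same alert stream.

## Q-learning controller

State s_t = [ŷ_t (2), r_{t+Δt}, CPUUsage_t, Energy_t] (5-dim for binary
classification).  Action grid: α ∈ {0.0, 0.1, …, 1.0} ×
β ∈ {0.0, 0.2, 0.4, 0.6, 0.8} (55 actions), which contains the two
documented operating anchors (0.3, 0.6) and (0.8, 0.4).  Reward weights
default to λ₁ = 1.0, λ₂ = λ₃ = 0.01 per ms-/mJ-equivalent, λ₄ = 0.5, with
the risk indicator strict (r > τ).  The Q-function is a two-layer network
with swish hidden activation; TD updates regress toward
R + γ·max Q_target with γ = 0.95 and a target network synced every 100
updates; replay is a 10,000-entry circular buffer sampled uniformly
without replacement.  ε decays linearly 0.1 → 0.01 over the first 1,000
steps and stays at 0.01 thereafter (including frozen evaluation — the
deployed policy retains residual exploration by design).

The action chosen at window t reconfigures inference for window t + 1
(causal ordering of the five-step loop: infer → update GP → forecast →
select action → adjust architecture).  One simulated session is one
episode; one window is one step.

## Resource proxy

MAC counts are analytic: pointwise T·C_in·C_out and depthwise T_out·k·C
per CNN block; 4H(C_in + H) per LSTM step scaled by (1 − β) on the
prunable matrices; branch MACs vanish at α ∈ {0, 1}.  Adaptation cost
(GP Cholesky ≈ n³/3 + solves, Q-network MACs, re-prune ranking passes)
is logged separately; adaptation overhead is 100 × adaptation MACs /
total MACs.  The ms- and mJ-equivalent scales are calibrated so the full
ensemble at (α = 0.5, β = 0) maps to 26.4 ms-equivalent; these constants
shape the reward landscape only and are never reported as measured
performance.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of an athletic ankle-IMU corpus:
200 Hz sampling, six scenario segments with distinct second-order
statistics (harmonic gait at 1.4 Hz stride for steady running, yaw bursts
for directional changes, quiet flight + broadband landing impacts for
jumps, impulsive collisions, linearly growing variance under fatigue),
four injury categories at proportions 62.5/16.8/12.6/8.0 %, a linear-ramp
pre-injury drift on type-specific axes (roll gyro for inversion/eversion,
yaw gyro for rotational, acceleration magnitude for impact; 0.5 s window),
and explicit partial sensor dropout.  Default cohort for the packaged
experiments: six subjects × 60 s at 4 events/min — event-dense relative
to field rates so that desk-scale runs contain enough positives for
stable metrics; test-suite benchmarks use ten held-out 30 s sessions.

It does **not** emulate: biomechanically validated musculoskeletal
dynamics, real sensor noise spectra or calibration error distributions,
inter-subject kinematic variability beyond phase/seed differences, or the
morphology of any real recording.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the adaptation
mechanisms move the documented directions on data with the stated
structure — not field performance on real athletes.

## Numerical choices and degenerate inputs

- GP posterior: exact agreement (≤ 1e−8) with a dense inverse-formula
  oracle is enforced for n ≤ 10; non-PSD covariances fail loudly after
  jitter escalation.
- Quantizing an all-zero tensor sets scale 1 and round-trips exactly.
- Pruning at ratio 0 is the identity; ratio ≥ 1 is rejected.
- Streams shorter than one window yield an empty window list; trailing
  partial windows are discarded.
- Events earlier than 200 ms into a session label only the available
  history and log a warning.
- FAR with zero alerts reports 0 % with a warning; IDA/APA with zero
  events are undefined and raise.
- Alert episodes merge within 200 ms before matching; the event match
  window is [event − 1000 ms, event + 100 ms] (the lead rule defines the
  advance threshold, the late bound is a design default).
- APA uses the inclusive "at least 150 ms before" rule; the
  "within 150 ms" variant is available via `rule="within"`.
- FAR uses the per-alert denominator (alarm-precision complement); a
  per-window variant is available via a flag.

## Known limitations

- The ensemble branches are numpy implementations sized for 40 × 6
  windows; they are not meant for large-scale training.
- The GP is univariate-in-time per feature; cross-feature correlations in
  the forecast are ignored.
- The resource model counts MACs, not memory traffic or cache behavior;
  proxy-calibrated "latency" is not device latency.
- Policy-gradient controllers, sparse GPs, structured pruning, and
  hardware int8 kernels are out of scope.
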