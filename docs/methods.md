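# Methods

This note documents the models and procedures implemented in `fingerctx`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Session model and conventions

Time is integer milliseconds from session start; all windows are half-open
`[start, end)`. This matches the 1 ms cadence of the spiking-band-power
(SBP) stream and avoids floating-point drift when concatenating trials.
Finger position is percent flexion on a 0 (full extension) to 100 (full
flexion) scale, with two columns: the index finger and the
middle–ring–small (MRS) group. Velocities are %/s.

A session is one HDF5 container holding a column-typed trial table
(`/trials`), the continuous streams (`/streams/sbp_1ms`,
`raw_count_1ms`, `finger_pos`, per-channel `crossings/ch###`, optional
EMG), and `monkey_id` / `n_channels` / `schema_version` attributes. Block
labels are stored explicitly per trial rather than inferred, because
z-scoring and context alternation depend on them. A plain-CSV trial-table
writer exists for tiny fixtures.

Trial selection for every offline analysis drops unsuccessful trials and
the trial immediately following one (a re-presented center target with
atypical initial conditions).

For online-mode trials the `finger_position` stream holds *decoded*
positions; the trial's `mode` field flags this.

## Synthetic-session generator

The generator emulates the conditions of a context-change experiment:
center-out-and-back finger movements (out targets alternate with the
center at 50%; the center is re-presented after any failure), context
blocks (normal / spring / wrist / band / both), and 96-channel neural
features driven by low-dimensional latents. Defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| `n_channels` | 96 | — | Utah-array channel count |
| target magnitude (tuning task) | ±40 | % RoM | tuning/geometry task geometry |
| `target_width` | 15 | % RoM | target spans 15% of the range |
| `hold_time_ms` | 750 (offline) / 500 (online) | ms | task timing |
| `movement_duration_ms` | 500 | ms | gives ≈150 %/s peak speed |
| `reaction_time_ms` | 200 ± 50 | ms | primate reaction times |
| `trials_per_block` | 175–350 | trials | context alternation granularity |
| `fraction_failed` | 0.05 | — | failures are rare |
| spring gains (flexor, extensor) | 1.92, 0.92 | × | ≈ +92% flexor, −8% extensor activation |
| wrist gains | 1.53, 0.68 | × | ≈ +53% flexor, −32% extensor |
| band gains | 1.50, 0.90 | × | rubber bands ≈ weak springs (chosen) |
| both gains | 2.45, 0.63 | × | compounding of spring and wrist (chosen) |
| co-contraction | 0.35 (spring) | × | extensors recruited during resisted flexion |
| `context_shift_scale` | 1.0 | — | see below |
| `noise_sd_sbp` | 0.5 | a.u. | per-ms pre-rectification noise |
| `baseline_drive` | 1.5 | a.u. | keeps channel drive mostly positive |

Kinematics are minimum-jerk (single-peaked speed, peak `15A/(8T)`), with
failures modeled as half-way undershoots. Muscle envelopes are
`baseline + gain·rect(velocity)` per muscle group, with the co-contraction
term adding flexion-velocity-locked extensor activation off-context. Raw
10 kHz EMG (optional, `emg_mode="raw"`) is 100–500 Hz band-limited noise
amplitude-modulated by the envelope and normalized so the binned mean
absolute value recovers the envelope; by default only the 1 kHz envelope
stream is stored, because a session-length 10 kHz × 8 array is bulky and
the downstream analyses consume the binned envelope either way.

Latent layout (16 latents, 9 active): one condition-independent
trial-phase latent (normalized speed), four signed target latents
(position and velocity per finger group), two context latents, and two
target-by-context interaction latents. The **leading context latent is the
difference between the active muscle group's required envelope and its
normal-context counterpart** (flexors while flexing, extensors while
extending); the second carries the non-active group (co-contraction).
Both are identically zero in the normal context *and whenever all context
gains are 1*, which is what makes null calibration meaningful. The
interaction latents scale with `(gain − 1)` for the same reason. Because
the context latent derives from the muscle-activation difference, the
correlation between the leading context component and active-muscle
activation is an emergent, recoverable property — nothing in the analysis
code knows the construction.

`context_shift_scale` (default 1.0) sets the context latent's amplitude
relative to the kinematic latents. The default keeps the context effect
detectable per channel while small enough that the context latent does not
leak appreciably into decoders trained on normal trials; at this setting
the off-context amplitude-ratio statistic recovers the planted gain
(tested), and the context marginalization carries of order 1% of
condition-average variance — smaller than in the recorded data, a known
scale-down of the synthetic conditions.

Neural observations: channel drive = `baseline + loading @ z` with
`loading ~ N(0, 0.4²)`; SBP is the rectified drive plus Gaussian noise
(two 2 kHz samples per millisecond), and threshold crossings follow an
inhomogeneous Bernoulli/Poisson process with rate
`25 · softplus(drive − baseline)` Hz. The softplus link and the rate scale
are modeling choices (no quantitative SBP↔rate coupling is prescribed);
the scale keeps typical channels above the 1 Hz masking threshold. One
global seed expands into named child seeds per stream, so any single
stream regenerates reproducibly.

## Feature extraction

- `bin_sbp`: bin value = Σ per-ms rectified sums / Σ raw sample counts;
  trailing partial bins are dropped, never zero-padded; a zero-count bin
  yields 0 with a logged warning.
- `bin_tcfr`: events per bin / bin width, in Hz.
- `remove_artifacts`: any millisecond on which ≥ 20 channels carry an
  event is cleared on all channels (idempotent).
- `emg_envelope`: second-order Butterworth 100–500 Hz band-pass applied
  **causally** (as acquisition hardware would), then per-bin mean absolute
  value; a zero-phase option exists for offline parity studies.
- `gaussian_smooth`: "100 ms kernel" is read as σ = 100 ms (the common
  convention), truncated at ±3σ, unit-sum with edge renormalization; an
  FWHM reading is available via `kernel_is_fwhm=True`.
- `savgol_velocity`: positions decimated to the 20 ms grid, smoothed with
  a second-order Savitzky–Golay filter (window 7 points = 140 ms, not
  prescribed, exposed as a parameter), velocity by central differences —
  exact on polynomials up to the filter order.
- `find_peak_movement`: speed is the Euclidean norm over active finger
  groups (single-group speed is an option for 2-DOF); the largest local
  peak after presentation wins, earliest on ties; a monotone trace returns
  the global maximum flagged degenerate.
- Peri-movement averages use 10 + 1 + 10 bins of 20 ms (420 ms); manifold
  windows use 20 + 1 + 37 (400 ms before to 740 ms after the peak bin).

The tuning regression consumes **unsmoothed** 20 ms bins: its
per-coefficient t-tests assume approximately white feature noise, which
kernel smoothing would violate (smoothing is used by the peri-movement
activity comparison, not the tuning fit).

## Tuning and context modulation

Per channel: features and kinematics in 20 ms bins over concatenated
normal + off-context analysis trials; the feature is z-scored over the
combined data (so positive channel rescalings cannot change any call); the
optimal lag (±10 bins) maximizes the 2-norm of the OLS coefficients from
feature to [position, velocity], ties preferring small |lag|, negative
first. The fit `Y = B + [x̂, c·x̂]·W` is least squares column-wise with
residual-based standard errors on `T − 3` degrees of freedom. 1-DOF tuning
uses the index trace.

FDR: all four coefficients of every channel are pooled into one
Benjamini–Hochberg family per session at level 0.001 — the conservative
reading of a per-session correction; a per-row option exists. *Tuned* =
either first-row coefficient survives; *context modulated* = either
second-row coefficient survives; summary percentages are computed among
tuned channels. The optimal lag is fit on the concatenated both-context
data (normal-only is an option).

## Offline decoding

Channels are masked to mean session TCFR > 1 Hz. Features are 32 ms SBP
bins with 12 history bins per channel; the first 12 rows of each trial are
dropped so no design row crosses a trial boundary. Features are
standardized with training-fold statistics only. The ridge penalty is not
prescribed; the default is chosen per fold by generalized cross-validation
on the training folds (a fixed-λ override exists for strict
reproducibility studies). The intercept is never penalized.

Folds partition normal-trial bins into contiguous trial blocks of
near-equal bin counts — trial-boundary splits respect autocorrelation
while matching equal-bin-count folds as closely as trial granularity
allows. Each fold's model is scored on its held-out normal bins and on
*all* off-context bins; summaries report per-fold and mean ± sd metrics
plus percent changes against held-out normal.

Metrics: Pearson r per output, and nMSE = MSE / population variance of the
measured test data, which equals 1 − R² (the fraction of unexplained
variance); the constant-mean predictor scores exactly 1. EMG targets are
100 ms-smoothed envelopes on the 32 ms grid; negative predictions are not
clipped before metric computation. Kinematic targets are position and
velocity of both groups fit jointly, with per-output metrics.

The off-context amplitude ratio (predicted / measured baseline-subtracted
peri-movement EMG amplitude, top-decile bins of the measured envelope)
estimates `1/gain` for the planted context gain. The estimator is
unbiased but inherits seed-to-seed variance from finite-sample leakage of
the context latent into the decoder weights, so headline numbers average a
few replicate sessions.

## Closed-loop simulation

The online decoder is a linear-Gaussian Kalman filter over
`[pos_i, pos_m, vel_i, vel_m, 1]` at 32 ms. The exact filter equations are
not prescribed by the source description; we adopt the standard
position/velocity form with an appended constant-1 state: position rows of
the transition matrix implement physical integration, velocity rows are
least squares, the observation model regresses features on the full state,
and noise covariances come from the residuals. Displayed position
integrates the posterior velocity, clamps to [0, 100], and is written back
into the state (position feedback). This is the module's largest
inference and the main caveat when comparing against any specific online
implementation. The 1-DOF case runs the same 2-D state with both groups
yoked.

ReFIT retraining rotates decoded velocities onto the unit vector from the
current position to the target center in the raw percent-flexion plane
(magnitude preserved), zeroes them whenever all fingers are inside the
target, and refits the observation matrix and noise covariance; the
transition model is untouched.

The intention model is a deliberately simple monkey stand-in:
- commands are re-planned at a 192 ms cadence (intermittent control) and
  aim to close 90% of the remaining gap within one interval, capped at
  200 %/s, with 10 %/s command noise;
- the relax rule: no corrective command while all fingers are inside the
  target;
- visual feedback is 128 ms old, but a forward model predicts the current
  position assuming the running plan executed as intended. When encoder
  and decoder match, the prediction is accurate and control is nearly
  delay-free; a context mismatch violates the prediction, producing
  overshoot and re-acquisition cycles — the mechanism by which the planted
  mismatch degrades acquisition times;
- an optional static re-aim offset models compensatory "pushing harder";
  it is off by default so planted mismatches first show raw costs.

The encoder mismatch applies the flexor gain to the velocity-driven drive
while the commanded movement is toward flexion and the extensor gain
toward extension (the neural correlate of the changed activation
requirement), plus an optional tonic shift along the context-loading
direction (off by default: its decoded direction is random across
loading draws, which makes small-simulation statistics noisy). Trials time
out at 10 s (configurable); hold is 500 ms online.

Online metrics follow the standard definitions: time to target = first
moment all fingers with targets are inside; acquisition = time of the
*final* entry (so acquisition ≡ time-to-target + orbiting exactly, and
never-left trials have orbiting 0); path efficiency = straight start-to-
target-center distance over traveled path length (can exceed 1 when the
path legitimately stops at the near target edge). Failed trials are
excluded from between-context comparisons but retained for adaptation
statistics. Adaptation scores z-score acquisition times within each
context block and average the first five; scores are standardized by the
without-replacement variance factor `(n−k)/(k(n−1))` so the one-sample KS
test against N(0, 1) is approximately calibrated across block sizes.

With this non-adaptive intention model, ReFIT retraining does not
reproduce the online improvement seen with a behaving subject: the
retrained observation model changes the loop gain that the (static)
forward model assumed. The ReFIT construction itself is verified at the
operation level (exact rotation, in-target zeroing, untouched dynamics).

## Population geometry

Trial tensors align each analysis trial to its peak-movement bin and take
58 bins of 20 ms (400 ms before to 740 ms after), channels masked by the
1 Hz TCFR rule; center-return trials are excluded. Trial averages per
(context, target) give each context's N × T × D tensor; reshaped to
N × (T·D) and channel-centered, the top-K PCA basis (default K = 16) is
that context's manifold. Principal angles are arccos of the singular
values of the basis cross-product, ascending. The control distribution
resamples two *disjoint* random sets of normal trials (default 50 per
set, 100 repetitions) and computes within-context angles — the sampling
floor against which cross-context angles are judged.

Demixed PCA: the balanced condition-average tensor (unequal per-condition
trial counts are balanced by seeded random subsampling to the minimum) is
channel-centered and split into four additive marginalizations — time
(condition-independent), context(+time), target(+time), and the
interaction remainder — which are mutually orthogonal under the balanced
averaging inner product and sum to the centered averages exactly. Per
marginalization, paired decoder/encoder maps solve a ridge-regularized
reduced-rank regression of that marginalization on the full
condition-average data (regularization 1e-6 × total variance, exposed);
the 16-component budget is split across marginalizations in proportion to
their variance fractions (at least one component for any non-degenerate
marginalization), which is our allocation rule — the reference
formulation leaves it open. Variance fractions are exact ratios of
marginalization power and sum to 1 by orthogonality.

The context-component-vs-muscle statistic projects the **context +
interaction** marginalization onto the leading context decoder (the
context marginalization alone is target-averaged by construction, so the
target-specific part of the context effect lives in the interaction
term), takes peri-movement means per (context, target) condition, and
correlates them with the active muscle group's mean envelope across
contexts within each target group. To keep the component's fitting noise
independent of the evaluation data, the component can be fit on half the
balanced trials and projected on the other half (`holdout_full`); the
headline correlations use this split-half form, and multiple sessions are
pooled after orienting each session's sign by its flexion-group slope
(component signs are arbitrary, as in any PCA-like method).

## Problem sizes

Tests and the acceptance script run on scaled-down sessions chosen as the
package's own working sizes: 16–48 channels and 30–80 trials per context
block for statistical checks, 200 trials per arm for closed-loop
comparisons, three 4-context sessions of 80-trial blocks for the pooled
geometry statistics. The generator accepts the full study-scale geometry
(96 channels, 175–350-trial blocks) unchanged.

## Known limitations

- The generator's neural model is a rectified linear readout of latents
  with additive Gaussian noise; it has no spiking-network dynamics, no
  adaptation or drift, no correlated channel noise, and its
  condition-independent structure is a single speed-locked latent.
  Passing tests show the *analyses* recover planted structure under these
  conditions, not that real cortical data satisfies them.
- The context marginalization's share of variance under default settings
  is of order 1%, smaller than in recorded data; the correlation and
  recovery properties are about directions and ratios, not about
  variance shares.
- The intention model neither learns nor re-aims by default, so online
  results quantify the raw cost of an unadapted decoder; behaving
  subjects partially compensate.
- The Kalman filter structure is a standard reconstruction, not a copy of
  any particular online implementation; absolute online numbers are
  simulator-specific, and only within-simulator contrasts are meaningful.
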