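# Methods

This note documents the models, defaults and design decisions behind
`neurocursor`: what is simulated, how the decoders are defined and
trained, which numerical choices were made where the design was open, and
what the synthetic results do and do not establish about real recordings.

## Coordinate system and timing

The cursor workspace is the unit square in *screen heights*, origin at the
bottom-left, y up. Pixel-specified geometry (the 43 px grid border, 1 px
cell gaps) is converted at a configurable 1080 px per screen height. All
decoding runs on a 10 ms bin clock (`BIN_S = 0.01`); 1 ms frames exist
only inside feature extraction. Cursor position integrates the decoder
output once per bin and is clamped to the workspace (the edge behavior is
a simulator choice; nothing in the decoding stack depends on it).

## Feature extraction

Voltage blocks are bandpass filtered 250–5000 Hz with a 4th-order
Butterworth — zero-phase for offline blocks, causal for streaming. The
upper edge is capped just below Nyquist so reduced sampling rates (down to
10 kHz, used in fast tests) stay valid; zero-phase filtering pads by
roughly three cycles of the low edge so block-boundary transients cannot
masquerade as spikes. Linear-regression referencing subtracts, per
electrode, the least-squares prediction of its signal from the other 63
electrodes of the same array; a rank-deficient predictor set falls back to
mean-across-array subtraction (logged). By least-squares optimality the
referencing never increases total residual variance on the fitting block.

Per 1 ms frame each electrode contributes (a) a threshold-crossing
indicator — the filtered signal reaches −4.5 × the electrode's RMS, with
RMS computed over the block, a choice made because the estimation window
of the online system is not constrained by anything in this package — and
(b) spike band power, the mean squared filtered voltage. Binning sums
crossings and averages power over 10 consecutive frames; a trailing
partial bin is dropped and logged.

### Normalization and gating

`FeatureNormalizer.fit` computes per-feature mean/std over the current
training set and excludes electrodes whose mean crossing rate is below
5 Hz. Two open points were resolved as follows:

* **Zero-variance features** are *not* excluded: an electrode firing a
  constant 100 Hz is informative-by-rate yet constant-by-feature, and
  excluding it would contradict the rate rule. Constant features receive a
  unit-std surrogate, so their z-score is 0 at every training value and
  bounded by the ±5 clip on any drifted input.
* **The noise gate** ("4 of the last 5 bins at ≥ 500 Hz or
  ≥ 25 000 µV²") counts the current bin among the 5 and is inactive until
  5 bins of history exist. 500 Hz translates to ≥ 5 crossings in a 10 ms
  bin — the smallest integer count reaching that rate. A gated electrode
  has both features replaced by their training means (z = 0) for that bin.

Transforms z-score, clip to ±5, and drop excluded electrodes' columns.

## Velocity decoder

The readout is `v_t = alpha * v_{t-1} + (1 - alpha) * beta * D f_t`
followed by the speed adjustment `o_t = s(|v_t|) * v_t / |v_t|` with
`s(|v|) = r * (|v| / r)**p`. Parameter meanings and defaults:

| parameter | meaning | default | units |
|---|---|---|---|
| `alpha` | smoothing weight, in [0, 1) | 0.9 | — |
| `beta` | speed gain | 0.2 | screen heights/s |
| `r` | speed-adjust crossover | 1.0 | screen heights/s |
| `p` | speed-adjust exponent, ≥ 1 | 1.0 (off) | — |

The recursion state carries the **pre-adjustment** velocity: `o_t` is
derived from `v_t` each bin but never fed back. The alternative (feeding
back `o_t`) compounds the nonlinearity across bins and changes the
geometric-convergence property that makes `alpha` interpretable; the
chosen form keeps `v_t` exactly a first-order filter of `beta * D f_t`.

Training uses intention estimation: in `unit_vector` mode the label is the
unit direction from cursor to target and bins with the cursor within
`near_radius` (default: the target radius) of the target are excluded; in
`position_error` mode the label is the raw displacement and every bin is
included. `D` is fit by ridge regression (penalty 1e-3 on the z-scored
feature scale — 512 features can exceed the sample count in the first
seconds of calibration, and an explicit small penalty keeps the problem
well-posed without noticeably biasing the fit later) with an intercept
(z-scoring makes it near zero, but click- and speech-locked baseline
shifts are real and the intercept absorbs them). After fitting, `D` and
the intercept are rescaled so the mean predicted speed over the training
bins is 1, which puts `beta` in screen heights per second.

## Click decoder

A binary logistic regression scores each bin; the two-row decoding matrix
is the antisymmetric parametrization of the underlying binary fit, and
probabilities come from the softmax of the two scores. A literal
normalize-scores-to-sum-1 mode exists behind
`probability_mode="sum"` for comparison but is ill-defined for
non-positive sums and not used. Exact ties predict no-click.

The smoother emits a click at the first bin where at least
`ceil(T * w)` of the last `w = L / 10 ms` predictions are click — `ceil`
because a required *portion* T is a minimum — subject to a cooldown `C`
since the previous emission. After emitting, the window clears, so the
requirement re-arms from scratch; with the defaults (T = 0.8, L = 70 ms,
C = 1.0 s) that is 6 of 7 bins. Click-count monotonicity in T and the
cooldown guarantee are enforced by property tests.

Labels for training come from target-entry episodes: each continuous stay
of ≥ 0.5 s contributes click labels in the window 0.5–1.0 s after entry
(implemented half-open at bin resolution, bins 50–99 after the entry bin);
other on-target bins are ignored, off-target bins are no-click.

## Calibration controller

* The background decoder is applied to every incoming bin; angular-error
  samples are skipped when the cursor is within `near_radius` of the
  target, where the toward-target direction is ill-conditioned and the
  simulated user intends to stop — the same exclusion the training labels
  use.
* The rolling tracker holds 20 s of samples with exponential recency
  weights of 5 s half-life (the recency form is a design choice; only
  "recent values weighted higher" is prescribed).
* Every 1 s the weighted mean maps linearly onto an assist level (1 at
  ≥ 80°, 0 at ≤ 60°) and assist is the running minimum of these levels —
  monotone non-increasing by construction.
* Assisted movement is `(1 - a) * o_t + a * assist_speed * unit(target -
  cursor)` with `assist_speed` defaulting to `beta`, so open-loop travel
  speed matches the decoder's eventual speed scale.
* Retraining runs every 2.5 s (the middle of the stated 2–3 s cadence) on
  all data in the current same-imagery series, refitting the normalization
  statistics each time; the live decoder and statistics swap atomically
  between bins, so telemetry has no gaps.
* Click assist auto-clicks after 1.5 s on target. A single continuously
  running shadow smoother evaluates the click decoder across trials; when
  ≥ 7 of the last 8 cued targets would have been clicked with ≤ 4
  off-target clicks, click assist turns off and stays off for the session
  (one-way, matching the described transition). The error tracker persists
  across block boundaries within a series.

## Synthetic cortex

Each of 256 units (4 arrays × 64; scaled down to 16 per array in most
tests) has a baseline rate U(8, 40) Hz, a uniform-random preferred
direction, a directional depth U(10, 30) Hz scaled per array by
{d6v: 1.0, area 4: 0.5, v6v: 0.2, 55b: 0.02}, and — on a random 30% of
units per array, equally across arrays — a click gain U(15, 40) Hz. Rates
are `max(0, baseline + depth * (pd . dir) + click_gain * click +
speech_drive)`; crossing counts are Poisson(rate × 10 ms) clipped at 10;
SBP is an affine, gamma-noised function of the same count so both feature
families are informative. The per-array multipliers plant the spatial
structure that the ablation analyses are designed to detect: one dominant
directional array, one moderate, one weak, one near-silent, with click
information everywhere.

**Speech modulation** (off by default; enabled for speech sessions with
`speech_frac = 0.5`) lands on the most directionally tuned units, which is
what makes speaking interfere with cursor decoding rather than just adding
noise. Each unit has a second preferred direction in an abstract 2-D
articulator space; a spoken word is a unit vector there, and the drive is
a signed cosine — like the movement term — with gain U(40, 100) Hz. The
gain range was chosen so the *decoded* perturbation while speaking is
comparable in magnitude to a full-speed movement command (ratio roughly
0.5–1), matching the qualitative observation this package emulates:
speaking visibly and transiently perturbs the cursor. Words last 1.0 s.

**The simulated user** reacts 0.2 s after each go cue, intends the unit
direction toward the target, intends zero inside a stop radius (the target
radius by default), raises click intent after 0.3 s on target in click
tasks, and speaks for 1.0 s from each speak cue. It has instantaneous
visual feedback and never fatigues — one reason simulated success rates
and bitrates exceed what a human user achieves at the same decoder
quality.

### What the generator does not model

No biophysics, no spike sorting errors, no electrode drift or
nonstationarity, no correlated (shared-latent) noise beyond the planted
tuning, no reaction-time variability, and no learning by the user.
Consequently, passing tests demonstrate that the *decoding stack and
controller logic* behave as specified under their own assumptions — not
that they would achieve any particular performance on real recordings.
Absolute numbers (bitrates, onboarding times, angular errors) are
properties of the synthetic conditions; only their qualitative structure
(array ordering, above-chance click information everywhere,
speech-condition ordering) is meant to generalize.

## Tasks

* **Radial8**: eight targets on a 0.35-screen-height ring at 45°
  intervals plus a center target (ring/target/cursor radii 0.35 / 0.06 /
  0.02 are simulator defaults — the task contract specifies only the
  layout); cues alternate center and outer, each 8 outer cues a fresh
  permutation; selection by continuous dwell (0.8 or 1.0 s) or click;
  10 s limit; the next cue is immediate. "Touching" is center distance ≤
  target radius + cursor radius; the dwell clock resets on exit. In click
  mode no dwell is additionally enforced.
* **Grid**: N² half-open cells `[left, right) × [bottom, top)` inside a
  43 px border, 1 px gaps; selection uses the cursor center point; clicks
  in border/gap select nothing; the trial's start cell is disabled for
  2.0 s or until first exit; wrong-cell selections end the trial as
  failures; timeout 10 s; the cursor position carries across trials.
* **Speech-and-cursor**: the Radial8 layout with word prompts; delay
  uniform 1.3–1.7 s before the go cue, dwell 1.5 s, intertrial 1.0 s;
  beep trials (probability 0.5, a simulator choice) schedule one beep
  uniformly 0.3–2.0 s after the go cue, moved up to 0.1 s after target
  entry if the cursor arrives first; verbal blocks schedule a speak event
  0.3 s after the beep.

## Offline analyses

Bitrate is `log2(N - 1) * max(correct - wrong, 0) / duration` — the
standardized grid-task formula. Velocity ablations retrain a decoder per
electrode subset on calibration telemetry and replay evaluation telemetry;
the per-trial statistic is the unweighted mean angular error over that
trial's move-period bins outside the near-target radius (bin weighting
within a trial is a free choice; unweighted is the simplest defensible
one). Click ablations classify window-mean features (the aggregation rule
over the 100 ms windows is likewise a free choice) with 5-fold stratified
cross-validation. Confidence intervals are percentile bootstrap over
trials/windows (10⁴ seeded resamples, bit-for-bit reproducible);
significance is one-sample t vs chance (90° or 0.5) and two-sample t vs
the all-array result, Bonferroni-corrected within each family, at
p < 0.01. Acquisition-time comparisons use two-sided rank-sum tests over
all condition pairs with Bonferroni correction.

## Problem sizes

Tests run the closed loop at 64 electrodes (16 per array) with a 90 s
calibration block and a 540 s grid session — enough trials for the
window-classification analyses to have statistical power at the corrected
p < 0.01 threshold. `scripts/acceptance.py` runs the full 256-electrode
scale: one 180 s calibration block, four 180 s grid blocks (two 6×6, two
14×14 with the speed adjustment engaged at r = 0.05, p = 1.5), and six
180 s speech blocks. These sizes are the package's chosen operating
points; everything scales with the configs.

## Known limitations

* The decoder bundle stores matrices as JSON arrays — adequate at this
  scale, not for very large models.
* The streaming (causal) filter path exists but the closed-loop simulator
  generates binned features directly; the voltage path is exercised
  offline.
* `evaluate_click_assist` trusts the shadow smoother's single stream;
  re-evaluating historical trials with the newest click decoder (rather
  than the one live at the time) might flip borderline windows.
* Sum-normalized click probabilities are provided for comparison only and
  can leave the [0, 1] range when the two scores have opposite signs.
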