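# Methods

## The model

`pflsteer.model` implements a rate model of the circuit that turns a fly's
head-direction signal and a stored goal direction into steering commands.

**Inputs.** Head direction is carried by a sinusoidal pattern of activity
across a population of units whose preferred directions **h** uniformly
tile 360°. Three output populations read shifted copies of this map:

- PFL3R: `cos(θ − θ0 − h + 67.5°)`
- PFL3L: `cos(θ − θ0 − h − 67.5°)`
- PFL2:  `cos(θ − θ0 − h + 180°)`

where θ0 is the (arbitrary, per-individual) anatomical offset of the
head-direction map. All three populations share a goal input
`A·cos(θg − θ0 − h)` with amplitude `A = 1` by default. Each unit's rate is
`f(S·(head + goal))`: the sum is scaled by the factor `S ∈ [0, 1]`, which
models the brain's control over the strength of goal-directed steering, and
passed through the activation `f`.

**Activation.** `f` is an exponential linear unit with pre/post rescaling:
the input is affinely mapped so the *lifetime ensemble* of inputs spans
[−1, 1], ELU is applied (`x` for `x ≥ 0`, `eˣ−1` below), and the output is
affinely mapped onto [0, 1]. The ensemble is all (θ, θg) pairs on a
1°-grid, crossed with every `S` configured for the run, and all unit
indices. For PFL cells the head and goal terms vary independently over
that product grid, so the extrema separate into per-unit sums of the two
terms' extrema and are computed exactly without materializing the grid.
For descending neurons the extrema are scanned over a 1° grid of
directional error — summed activity over a uniform preferred-direction
grid depends on θ and θg only through their difference (up to grid
discretization of order 1e−5 at 1,000 units).

The ELU is deliberately expansive: a single cell's goal input is a fixed
bias that pushes its operating point up the nonlinearity, amplifying its
head-direction tuning. Alternative activations are provided for robustness
checks (`relu`, `sigmoid`, `identity`). The sigmoid variant places its
half-maximum at +0.5 of the rescaled range: a logistic centered at the
midpoint is odd, which makes every population sum independent of bump
amplitude and silences the drive entirely — an instructive degenerate case,
not a usable model. With `relu` the drive has exact dead zones (bands of
zero output) around the goal. With `identity` the PFL2 contribution cancels
exactly in the right−left difference, which is the reason the circuit
needs a nonlinearity for PFL2 to influence steering.

**Wiring.** Descending-neuron inputs use population sums normalized to the
biological cell count: `Σ = 12 · mean(unit rates)`. There are 12 cells per
PFL population in the connectome; the 1,000-unit model is a smooth
interpolation of those 12, and normalizing the sums keeps the synaptic
weight ratios meaningful (an unnormalized 1,000-unit sum would make the
single DNa03 → DNa02 connection, weight 12, negligible against a
~500-unit direct sum, contradicting its anatomical rank as one of the
strongest inputs to DNa02). This also makes every population-level curve
invariant to `n_units`, verified at 12 vs 1,000 to within a few percent.

Weights (per connection type, from connectome synapse-count ratios):
PFL3→DNa02 = PFL3→DNa03 = 1, PFL2→DNa03 = 4 (bilateral, identical on both
sides), DNa03→DNa02 = 12. So:

```
DNa03R = f(ΣPFL3R + 4·ΣPFL2)        DNa02R = f(ΣPFL3R + 12·DNa03R)
DNa03L = f(ΣPFL3L + 4·ΣPFL2)        DNa02L = f(ΣPFL3L + 12·DNa03L)
```

The *direct* pathway is PFL3→DNa02; the *indirect* pathway is
PFL2/PFL3→DNa03→DNa02. Pathway ablations zero the omitted pathway's input
at the DNa02 summation while keeping the activation calibration fixed.

**Steering and the closed loop.** The rotational-velocity command is
`dθ/dt = k·(DNa02R − DNa02L)`, positive = clockwise. The gain `k`
(deg/s per unit DNa02 difference) is not constrained by the biology; by
default it is auto-calibrated so the peak noise-free open-loop |drive| at
`S = 1` equals 200 deg/s for the configured pathway set — the order of a
fly's turning speed. Calibration is per pathway configuration, because an
ablated configuration inherits a crippled dynamic range from the full
calibration and a shared `k` would make ablation comparisons trivially
weak.

Integration is explicit Euler at `dt = 0.1 s` (a 10 Hz update), wrapping
after each step. The noise term ε(t) is Gaussian, low-pass filtered at
2 Hz (second-order Butterworth applied forward–backward, zero phase — the
filter family is a package choice) and rescaled so its sample SD is
exactly `noise_sd` (default 10°). ε is a **per-update angular kick in
degrees**, added to the heading update without the `dt` factor. The
alternative reading (ε in deg/s, contributing `ε·dt` per step) is ~100×
weaker and cannot produce low-consistency runs at any `S`; the
degrees-per-update reading reproduces the observed spread of heading
consistency (ρ from ~0.2 at `S = 0.2` to ~0.85 at `S = 1`). The same seed
always yields an identical frozen noise trace, enabling seed-matched
comparisons across `S`.

**Emergent behavior** (all verified by the test suite, not asserted):

- The drive is antisymmetric in directional error, zero at the goal and
  anti-goal; the goal is stable and the anti-goal unstable.
- The indirect pathway's gain is concentrated around the anti-goal (PFL2
  pushes DNa03 into the steep part of the nonlinearity there) and is low
  near the goal. Consequently the full model converges without overshoot
  across the gain range explored, while the direct pathway alone — whose
  drive has an appreciable slope at the goal — develops error sign
  reversals (overshoot/oscillation) at 4× the calibrated gain. With Euler
  stability governed by `(local drive slope)·dt`, overshoot requires a
  slope above `1/dt = 10 /s`; at the default calibration the direct-only
  slope at the goal is ~2.9 /s, so the contrast is demonstrated at the
  top of the ×/÷4 gain band.
- In noisy closed loop, heading consistency ρ rises monotonically with
  `S`, the seed-matched contrast ρ(0.8) > ρ(0.2) holds in ~100% of runs,
  and ρ correlates positively with the range of error-binned PFL2 bump
  amplitude (rank correlation ≈ 0.8) — the model counterpart of the
  imaging result that strong goal fixation comes with strong
  bump-amplitude modulation.

Model PFL2 bump amplitude is measured by the same sinusoid-fit operation
as the imaging pipeline (`fit_bump` on the per-unit rate profile), so model
and data pass through identical code.

## Analysis pipelines

**Circular statistics** (`circular`). All angles are degrees in
(−180, 180], 0° = facing the cue, positive = clockwise. The goal direction
is the circular mean (atan2 of summed unit vectors) and consistency ρ is
the mean resultant length. Below ρ = 1e−9 the mean direction is flagged
undefined rather than returning an arbitrary angle. Argmax ties anywhere in
the package break toward the smallest bin index.

**Behavior** (`behavior`). Ball-position channels are unwrapped, low-pass
filtered (2nd-order Butterworth, corner 0.003 — interpreted as a fraction
of Nyquist since the units are ambiguous; exposed as a knob),
differentiated, clipped at 20 rad/s, smoothed by local quadratic
regression over 33 ms (Savitzky–Golay; exact MATLAB-loess equivalence is
not promised), resampled to 60 Hz, and converted (ball radius 4.5 mm;
cumulative speed = |forward| + |sideways| + |rotational| in ball rad/s,
mobility threshold 0.67 rad/s). Heading = −cue azimuth, lightly smoothed,
clamped at ±180° by default (wrapping is an option; circular statistics
wrap internally regardless). The sliding goal/consistency uses a 30 s
centered window, excluding immobile samples and 5 s after each cue jump.
Paths are segmented at dips of ρ below 0.88 (dips < 0.5 s lumped); segments
with ρ exactly 1 (frozen cue; tested as ≥ 1 − 1e−12) or without 2 s of
contiguous mobility are discarded; the pre-jump mean heading and ρ use
mobile samples only. Jumps are "corrected" if heading returns within
30°/60° (90°/180° jumps) of its pre-jump mean within 10 s — or 40°/75°
within 4 s under the alternate fast criterion — and "high ρ" at mean
pre-jump ρ ≥ 0.88. Conditioned binning uses 10 deg/s, 1 mm/s, 10° bin
widths; event-triggered averages are computed per fly first (≥ 4
repetitions per condition) and then across flies.

**Imaging** (`imaging`). Per ROI, ΔF/F uses the mean of the bottom decile
as baseline; the z layer is the median/MAD z-score of ΔF/F (MAD
unnormalized, so the z layer has median 0 and MAD 1 by construction; zero-
MAD ROIs are excluded with a warning). A 3-parameter sinusoid
`a·sin(x − u) + c` is fit per timepoint by linear least squares on a
sin/cos basis (closed form, deterministic); negative amplitudes are folded
by a 180° phase flip; adjusted r² uses `1 − (1−r²)(n−1)/(n−3)` with fits
below 0.1 flagged invalid. ROI centers are uniformly spaced over
(−180, 180], +180 = rightmost. Phase–heading coupling takes start-to-end
shortest-arc differences in 1.5 s bins with the heading led by 200 ms.
Neural goal inference bins bump amplitude by heading (5° bins), finds the
opposing-bin pair with the largest amplitude difference, and takes the goal
as the bin with the *smaller* amplitude; the amplitude range is max − min
of the binned amplitudes, with a 0.1 z-unit reliability floor (package
choice; a flat profile gives an arbitrary goal).

**Electrophysiology** (`ephys`). Baseline Vm: 50 ms median filter
(edge-padded) + 20 ms local quadratic smoothing. Spikes (method is package
plumbing — detection is not part of the scientific claim): positive peaks
of the residual above 4 robust SDs (1.4826·MAD) with a 2 ms refractory;
rate by 100 ms boxcar. IPSPs: the spike-filtered trace (25 ms median +
20 ms smoothing) yields a derivative and a 500 ms-median-detrended trace;
negative peaks of each (min separation 20 ms) are paired, and an event is
scored at a trough preceded by a derivative peak within 30 ms. Per-cell
thresholds default to 3 robust SDs of each signal's *noise floor*: the raw
noise SD is estimated from successive differences (robust to the events
themselves) and mapped through the pipeline's fixed noise gain, computed
once on a white-noise reference. A naive MAD of the derivative inflates
with event rate and collapses recall above ~10 Hz; the noise-gain
construction keeps the detected rate within 10% of truth across 2–20 Hz at
0.2 mV RMS noise and 1 mV events. Thresholds are floored at 15% of each
signal's range so noiseless traces do not admit filter-ringing artefacts.
Head-direction tuning uses 20° bins (θp = argmax bin, amplitude =
max − min); goal-offset analysis assigns segments (ρ ≥ 0.7) to 72° bins of
θg − θp, computes min-subtracted tuning curves against θ − θp, and negates
offsets for PFL3L before pooling with PFL3R. Jump ΔVm statistics compare
variances between corrected/high-ρ and uncorrected/low-ρ jumps with the
Brown–Forsythe test (scipy's Levene with median centering; validated
against the closed-form F and by type-I-error simulation). The
two-factor unbalanced ANOVA uses type-III sums of squares (statsmodels).
The Vm/steering lag correlation relates |ΔVm| in the 4 s after a
fast-corrected jump to rotational speed at lags −1…+1 s in 10 ms steps
(201 points); positive lags mean Vm leads.

## Synthetic data

The generators (`synth`) emulate the closed-loop virtual-reality protocol:
600 s trials, a cue jump every 60 s cycling +90°, 180°, −90°, yaw gain 0.7
(cue displacement = 0.7 × ball yaw displacement; the recorded ball yaw
velocity is the heading rate divided by the gain). Two behavior modes:

- **scripted** — a mean-reverting angular walk toward the scheduled goal
  (reversion rate κ per second, per-sample Gaussian noise), so
  behavior-pipeline tests do not depend on the network model. Defaults
  (κ = 1.5, 3°/sample at 60 Hz) give window ρ ≈ 0.97, a strongly fixating
  fly.
- **model** — the closed-loop network simulation at scale `S`, with cue
  jumps injected as instantaneous heading offsets and the 10 Hz trace
  upsampled to 60 Hz (the jump discontinuities are re-applied exactly on
  the 60 Hz grid).

Forward velocity is AR(1)-smoothed noise around 8 mm/s (realistic
magnitudes are not constrained by the experimental protocol; these are
plausible defaults, labeled as such), sideways around 0; immobility bouts
zero all velocities. Calcium fixtures produce the bump directly in
z-scored units (the analyses operate on z-scored data; photon noise is out
of scope) with phase moving opposite the turning direction and amplitude
laws "pfl2" (minimal at the goal), "pfl3" (maximal), or constant, plus a
positive affine raw layer for file round-trips. Vm fixtures sum a resting
potential, cosine head-direction tuning, a goal-bias term, IPSP kernels
(instantaneous drop, exponential recovery τ = 15 ms, amplitudes
0.5–2 mV — plausible ranges, not measured values; generated events are
spaced ≥ 25 ms so each is individually resolvable), optional
softplus-rate spikes rendered as 2 ms depolarizing templates, and Gaussian
noise. Every generator is seed-deterministic and records its ground truth.

What the fixtures do *not* emulate — slow drift of the head-direction
offset θ0, movement artefacts in Vm, bleaching, ROI cross-talk,
non-sinusoidal bump shapes — bounds what passing tests show about real
data: they demonstrate that the pipelines invert the generating model
class correctly at realistic noise, not that the model class captures
every property of fly recordings.

One limit surfaced by the generators: with the model's own noise level
(SD 10° per update), an `S = 0` fly's heading diffuses across the full
circle within a 10 s window, so it crosses the jump-return tolerance by
chance and the "corrected" label saturates. The no-steering control for
jump classification therefore uses the scripted mode with κ = 0 and slow
drift, where the corrected fraction is ~0 as intended.

## Numerical choices and problem sizes

- All trig in radians internally; angles stored in degrees throughout.
- Bump fits are closed-form least squares; no iterative optimization
  anywhere in the analysis path.
- The sweep used by the test suite runs 100 s of simulated time per
  (S, seed) pair — 50 matched seeds at S ∈ {0.2, 0.8} plus 10 seeds across
  five S values — which characterizes the ρ–S relationship well while
  keeping the suite under a minute of model time.
- Monte-Carlo calibrations: 2,000 noisy bump fits (phase recovery), 1,000
  Brown–Forsythe replicates (type-I error), 200 simulated cells (θp
  recovery); all seeded.
- Sub-sample timing: event times are converted to indices by rounding,
  never truncation.

## Known limitations

- The proportionality constant of the steering command and the amplitude
  units of model rates are conventions (only curve shapes and signs are
  constrained); quantitative deg/s outputs depend on the `k` calibration
  target.
- Model ρ is computed over the full run including the initial transient.
- The heading clamp at ±180° reproduces the acquisition convention; any
  samples at the clamp rail carry reduced information, and circular
  statistics treat them as ±180° exactly.
- The IPSP detector's per-cell thresholds are calibration choices; the
  30 ms derivative–trough coincidence rule and 20 ms peak separation are
  fixed by the analysis definition.
- `tuning_by_goal_offset` mirrors PFL3L by negating its goal offset; the
  tuning curves themselves are computed against θ − θp and are not
  additionally mirrored.
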