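# Methods

## The assay and its idealization

A suction needle in a shallow water layer draws larvae toward it. The flow
is idealized as a depth-averaged two-dimensional point sink: with volumetric
rate `Q_v` (mm³/s) and depth `h` (mm), the *surfacic flow rate* is
`q = Q_v / (2πh)` and the fluid moves radially toward the sink at speed
`q/ρ`, where `ρ` is the distance to the suction point. Walls, the platform
edge and fish–fluid back-coupling are ignored. The nominal imaging
conditions are a 22 × 18 mm field of view sampled at 35 µm/pixel and 250 Hz,
bright larvae on a dark background.

Positions are in millimetres in the arena frame, times in seconds, angles in
radians (see `UNITS.md`). The body angle `α` is measured from the **outward**
radial direction to the head axis, so `α = 0` is perfect counterflow
orientation; this convention is forced by the impulse model, in which a bout
of speed `u` changes the radial position by `+λ u cos(α)` — positive (away
from the sink) for a counterflow bout. Whether the original assay used the
inward or outward reference is not derivable from its description; the
outward convention is an inference, and the passive module exposes a sign
switch so both can be explored.

## Posture from image moments

Each frame is background-subtracted, smoothed with a Gaussian (175 µm box,
σ = 50 µm, converted to pixels and rounded up to an odd box), thresholded
(Otsu on the smoothed difference by default) and split into 4-connected
components; components under 500 px (≈ half a larva at nominal scale) are
discarded. The background is the run's average image by contract
(`build_background`); the pipeline itself defaults to a pixel-wise low
percentile (q = 10) over the run, because with only a handful of larvae that
hold position for most of a short synthetic session, the mean (and even the
median) retain "ghosts" of the larvae that bias centroids by up to a
millimetre, while a low percentile of a bright-on-dark scene recovers the
empty arena under any per-pixel occupancy below ~90%. The estimator is a
configuration choice (`SegmentationParams.background_method`).

A blob's *equivalent ellipse* shares its intensity-weighted centroid and
second central moments (a filled ellipse with semi-axes `a, b` has second
moments `a²/4, b²/4`; a per-pixel variance of 1/12 px² is subtracted for
flat within-pixel sampling). The body is split by the plane through the
global centroid perpendicular to the global major axis (a level-1 binary
space partition); the head is the heavier half (the head lobe is wider), or,
when a previous pose exists, the half nearer the previous head center. The
head ellipse's axis is resolved to point from the split plane outward
through the head half's centroid.

Signed curvature: the two halves' minor-axis lines intersect at the center
of curvature `C`; the radius `R` is the mean distance from `C` to all body
pixels and `κ = ±1/R`, positive when `C` lies right of the head direction
(right-handed with the image axes). Minor axes parallel within 0.5° give
κ = 0; |κ| is capped at 2 mm⁻¹. On rendered arcs this recovers |κ| within
~3 % and the sign exactly.

## Tracking

Frame-to-frame linking minimizes total squared displacement with a hard
gate of 3.5 mm per step, solved exactly per frame pair (Hungarian
algorithm). Tracks missing detections stay claimable for 100 frames
(400 ms); gaps are left absent, not interpolated. Automatic curation
replaces manual triage: tracks shorter than a minimum duration are dropped
and tracks are truncated where two larvae approach within 2 mm.

## Bouts and the impulse model

Swim bouts are detected on the curvature trace: `κ̇` by central differences
(reflected ends), its standard deviation over a sliding 20 ms window,
normalized by a quiet baseline — within each centered 400 ms window, the
mean of the values lying strictly below that window's median. A bout is a
run of normalized activity above 5 lasting more than 40 ms. Tail beats are
excursions of the curvature relative to its pre-bout baseline (mean over
the 100 ms before onset) beyond 0.1 mm⁻¹, one beat per pair of
sign-alternating excursions; the beat period is twice the mean peak
spacing.

Per bout, the time of minimum `ρ` inside the bout interval defines the
impulse start `t_k` (argmin taken on a 5-sample median-filtered copy so one
noisy sample cannot shift it). An affine fit on the 100 ms before `t_k`
gives the fluid speed `v_f` (reported positive toward the sink) and the
intercept; `ρ_k` is the affine value at `t_k` rather than the raw sample —
the raw minimum carries a ~1.5 σ selection bias that would dominate the
impulse-speed error at pixel noise. The 300 ms after `t_k` (truncated at
the next bout) are fitted by

    ρ(t_k + Δ) = ρ_k + λ u cos(α) (1 − e^(−Δ/λ)) − v_f Δ

with only `u ≥ 0` and `λ ∈ [4, 500] ms` free (`v_f` and the onset `α`
fixed), bounded least squares with multi-start at λ ∈ {20, 40, 80} ms.
Noiseless traces are recovered to ~10⁻¹⁴ relative error; at 1-pixel
Gaussian noise and 250 Hz the median errors are ≈ 3 % on `u` and ≈ 6 % on
`λ`. For a bout whose onset angle points toward the sink the model can only
explain an outward displacement with `u = 0` (the bound), which is the
intended behavior of the automated counterflow test below.

## Passive reorientation

An elongated body in the sheared sink flow experiences a Jeffery-type
torque. The passive module integrates

    dα/dt = sign · q L / ρ^p · sin α,   dρ/dt = −q/ρ

with RK45 (tolerances 10⁻⁹/10⁻¹², early stop at ρ = L). The printed form
of the rate is `qL/ρ` (p = 1, the module default, with the frozen-ρ closed
form `tan(α/2) = tan(α0/2) e^{qLt/ρ0}` as oracle). Two caveats are
surfaced rather than silently corrected: (i) `qL/ρ` has units of mm²/s,
not s⁻¹ — `p = 3` is the dimensionally consistent variant and gives
reorientation time scales of seconds to tens of seconds at the assay's flow
rates, matching the qualitative observation that passive alignment is a
minor effect; (ii) under the outward-α convention the `+sin α` term makes
facing the sink (|α| = π) the attractor, while the observed behavior
(onset angle distributions more peaked than offset ones) implies
stabilization around α = 0, i.e. the opposite sign. Both the sign and the
exponent are parameters.

## The synthetic assay

`simulate_session` is the testbed standing in for the recordings: point
larvae with a heading and an instantaneous curvature, advected by the sink
flow, performing discrete bouts. All randomness derives from one session
seed through named substreams (placement, scheduling, kinematics) and the
rendering noise from its own seed, so sessions are bit-reproducible.

* **Exploration**: bouts at exponentially distributed intervals (mean 1 s,
  a typical spontaneous swim pace) toward uniformly random headings.
* **CSS trigger**: the first bout scheduled 0.1–0.3 s (a reaction delay)
  after the larva first drifts inside the trigger radius (default 8 mm)
  starts the counterflow swim sequence; the phase label flips there.
* **CSS bouts** aim at the outward radial direction with 10° Gaussian
  scatter. Pacing is radius-triggered: the next bout fires when advection
  has carried the larva back to the radius where its CSS started (with a
  100 ms refractory floor and a 2.5 s cap). This reproduces position
  holding by construction — a per-bout timer scheme was tried first and
  leaked inward systematically at high flow. Inter-bout intervals then
  emerge at ≈ 2.2 s, 0.7 s and 0.3 s at 0.07, 0.22 and 0.44 mL/s.
* **Impulses**: speed `u ~ N(20, 4)` mm/s, damping `λ ~ N(40, 8)` ms,
  `n ~ Poisson(5)` beats of period `τ_b ~ N(25, 3)` ms, mean |κ| ≈ 0.2 mm⁻¹
  — magnitudes in the range reported for larval zebrafish slow swims. The
  velocity is `u e^{−Δ/λ}` along the heading, which reproduces the impulse
  response exactly; the heading turns linearly over the first beat. The
  curvature waveform is a signed sinusoid of `n` periods whose mean
  absolute value matches the bout's |κ| (amplitude = π/2 · |κ|).
* **Between bouts**: advection `ρ̇ = −q/ρ` plus passive reorientation with
  the stabilizing sign and p = 3 (see above) — the variant under which the
  generator reproduces the reported statistical structure (exploration
  circular variance ≈ 1, passive orientation a minor effect, onset angles
  slightly more peaked than offsets).

Rendering paints each larva as a flat-top intensity stamp of its width
profile along a circular arc of the pose's curvature, with a one-pixel
antialiased edge (~1040 px at nominal scale, consistent with the 500 px ≈
half-larva size filter). The arc is anchored so that the tangent at the
head-axis reference point equals the pose heading and the width-weighted
centroid sits at the pose position; the reference arclength is computed
once per body model so that the continuum head-half principal axis
coincides with the local tangent, closing the render→measure loop to
< 1 px in position and < 1.5° in heading up to |κ| = 0.5 mm⁻¹. Additive
Gaussian pixel noise is drawn from a precomputed unit-variance bank with
random per-frame crops (per-pixel marginals are exactly Gaussian; distant
frames may reuse values — irrelevant for the detection statistics tested).

What the generator does **not** emulate: hydrodynamic fish–fluid coupling,
3-D posture and depth, wall effects, multi-larva interaction, appearance
variation between individuals, illumination drift and camera vignetting.
Passing tests therefore validate the *pipeline* (measurement, detection,
fitting, statistics) under the stated model, not biological conclusions
about real recordings.

## Population statistics

Circular variance is `1 − |mean resultant|`. CSS labeling is automated
(the original study curated manually): the onset is the first bout opening
a run of ≥ 3 bouts with |offset α| ≤ 45° and `u cos(α_onset) > 0`; all
three parameters are exposed. Because the onset angle of the very first
CSS bout is measured before the orienting turn, that bout can fail the
impulse-direction test and the label then lands one bout later — with a
position-holding generator this changes the onset radius negligibly.

Onset-aligned circular-variance curves pool angles into 0.5 s bins over
±10 s around each track's onset, in per-bout (the printed definition) or
per-frame mode; bins under `n_min` samples are masked. KDEs use fixed
Gaussian bandwidths (defaults per quantity: 0.75 beats, 1 ms, 0.01 mm⁻¹,
2 mm/s, 75 ms, 0.25 mm) on a grid extended 6 bandwidths beyond the data
with steps fine enough for the trapezoidal integral to be 1 within 10⁻⁶.
Two-sample tests are Kolmogorov–Smirnov (asymptotic p by default, exact
available) and Welch's t; significance stars at p < 10⁻³ and p < 10⁻⁶.
Standard errors are sample std/√n; bins or groups with n < 3 are masked.
The egocentric map histograms the sink position in the head-forward frame
(sink at angle π − α, radius ρ; +x ahead, +y to the larva's left).

## Problem sizes and numerical choices

The validation suite runs entirely on synthetic data at desk scale: six
rendered sessions of four larvae at 0.07/0.22/0.44 mL/s (12–18 s each,
250 Hz, ~22 000 frames in total) for the end-to-end checks; 5 × 35 s
ground-truth traces (≈ 260 bouts) for detector performance; 2 × 200
synthetic impulse responses for fit recovery; 10 larvae × 2500 frames for
the tracking audit. Start positions sit in the field-of-view corners
(ρ ≈ 10.7 mm), the farthest the 22 × 18 mm field allows with a body-size
margin, so that several exploration bouts precede the trigger crossing.
Degenerate inputs are defined, not special-cased: constant curvature gives
zero activity (flagged), beatless bouts give n = 0 (flagged), short
post-bout windows leave kinematics unfit (flagged), near-parallel minor
axes give κ = 0, and isotropic blobs carry an unconstrained-orientation
flag.

## Known limitations

* The printed passive-rotation rate is implemented verbatim; its
  dimensional inconsistency and attractor sign are documented switches,
  not resolved facts.
* The automated CSS label approximates a manual curation step; its
  parameters shift the measured onset by up to one bout.
* The experiment's headline numbers (counts of sequences, the 8.7 mm
  operating point, onset-angle spreads) depend on the original recordings
  and are out of scope; grouped summaries expose the hooks (flow rate,
  age) without modelling development.
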