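# Methods

## Task geometry and conventions

The workspace is a 2-D plane. A rigid stick of length 40 cm is held at its
left end (left hand) and 15 cm to the right of it (right hand); the
controlled end-effector is the right tip, 40 cm from the left hand (L) and
25 cm from the right (R). Angles are degrees at every API boundary,
counter-clockwise (CCW) positive; stick tilt 0° means the stick lies along
+x with the tip to the right. The stick direction vector points from the
left end to the tip, so tip = left + L·u(θ), which makes the hand-path cost
decomposition below read off directly from the kinematics. Coordinates are
relative to the tip's start position of the current trial unless a trial
table supplies absolute positions. The grip is treated as rigid; the real
apparatus enforces hand separation with a stiff virtual spring, and grip
dynamics, forces and within-trial feedback corrections are out of scope.

## Minimum-hand-path-cost model

For a target at direction φ and distance d (default 10 cm), and a final
stick tilt θ reached at the end of the movement, straight point-to-point
hand paths have total length

f(φ, θ) = √((d cosφ − L cosθ + L)² + (d sinφ − L sinθ)²)
        + √((d cosφ − R cosθ + R)² + (d sinφ − R sinθ)²).

At θ = 0 both hands translate by d, so f = 2d for every φ. The model's
predicted tilt θ*(φ) solves ∂f/∂θ = 0. Minimisation is a bounded scalar
search on θ ∈ [−89°, 89°] (derivative-free Brent), polished by root-finding
the analytic derivative within ±1° of the bracket minimum; results satisfy
|∂f/∂θ| < 1e−8 cm/deg and are verified in the tests against an exhaustive
0.0001°-step grid. The bound keeps the search away from degenerate
geometry; physical tilts in this task are below 10°. By the symmetry
f(−φ, −θ) = f(φ, θ), θ* is antisymmetric in φ, and over the nine protocol
targets the (φ, θ*) pairs form a strictly increasing, mildly nonlinear
curve (≈ ±6.6° at φ = ±30°) — the model-side counterpart of the baseline
TMD–STA relationship.

## Baseline TMD–STA relation

The empirical relation g maps tip-movement direction (TMD) to stick-tilt
angle (STA), both read out at the tip's peak velocity. It is represented as
a monotone piecewise-linear interpolant: baseline trials are binned by
nominal target direction, knots are per-bin means, and monotonicity is
enforced by pooling adjacent violating bins (isotonic regression weighted
by bin counts). Outside the outermost knots the end segments extrapolate
linearly. Piecewise-linear was chosen over splines because no functional
form is prescribed, only monotone increase, and because the learner needs a
well-defined local slope g′; at a knot the slope is the mean of the
adjacent segment slopes. Peak velocity (not movement offset) is the default
read-out epoch for fitting, matching the default read-out of the analysis
chain. Per-participant relations are fitted from that participant's
baseline trials; a population relation can be formed by averaging knots.

## Visual perturbations

All perturbations act on the display only. With ρ(t) the tip-rotation
magnitude at adaptation trial t (1-based) and k = 0.6°/cm the tilt gain:

- tip rotation: visual tip = start + Rot(ρ)·(physical tip − start);
  gradual mode ρ(t) = min(t·1°, 30°), abrupt mode ρ(t) = 30°. The displayed
  tilt is unchanged.
- tilt about the tip: visual tilt = physical tilt ± k·r, where r is the
  tip's displacement from the start; the displayed tip is unchanged. The
  ramp is linear with no cap — the movement ends at r = 10 cm where the
  offset is ±6°, and no behaviour beyond that displacement is defined.
- combined: both applied.

On the (TMD, STA) planes the map is a horizontal shift by ρ and a vertical
shift by ±k·r, where r is the displacement at the read-out epoch:
mid-movement read-outs see a partial tilt offset (±3° at peak velocity),
end-of-movement read-outs the full ±6°. Because rotation about the start is
an isometry, r is frame-invariant and the pose-level map is bijective with
a closed-form inverse. States carry a frame tag (physical/visual) and
cross-frame arithmetic is rejected.

## Trial kinematics

Tip trajectories are straight paths with the minimum-jerk displacement
profile r(τ) = d(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T: any unimodal bell-shaped
profile would do, and the quintic has closed forms (r(½) = d/2, peak speed
1.875·d/T at τ = ½) that the tests use as oracles. Default duration
T = 0.5 s and sampling dt = 1 ms put the peak speed at 375 mm/s, inside the
300–450 mm/s feedback band; per-trial durations are drawn from
N(0.5, 0.03²) s, clipped to [0.35, 0.65] s. The stick tilt ramps in
proportion to displacement, reaching the planned final tilt at the target —
consistent with the displacement-proportional tilt perturbation and with
monotone within-movement tilt growth; the true within-trial tilt time
course is not constrained by available data, so this ramp is a modelling
choice. A consequence handled consistently throughout: the peak-velocity
STA read-out of a synthesised trial is half the final tilt (half
displacement), so when plane-level states (defined at peak velocity) are
realised as kinematics, the synthesiser ramps to twice the planned STA and
the analysis read-out returns the planned value. Hands are derived from the
(tip, tilt) pose at every sample, so the rigid-stick invariant holds
exactly.

## Constrained-correction learner

State: the planned physical intent x = (m, a) — TMD and STA at the plan
level. Per trial: executed = intent + motor noise; the executed state is
seen through the perturbation map at the end-of-movement displacement
(where the tilt offset is the full ±6°, the magnitude the participant
ultimately observes); two errors are computed from the seen (visual) state:

- task error e_m = target − TMD_vis,
- tilt error e_a = g(TMD_vis) − STA_vis (the dissociation between the tilt
  predicted for the seen tip direction and the seen tilt).

The correction is constrained to the baseline relation: with s = g′(m) and
unit tangent t = (1, s)/√(1+s²), the update is

x ← x_base + (1 − λ)(x − x_base) + ((η_m e_m, η_a e_a)·t) t,

i.e. the weighted error vector is projected onto the relation tangent, and
retention (λ) decays the intent toward the baseline intent x_base for the
current target (the relation point (target, g(target))), not toward zero.
The projection is the package's formalisation of the hypothesis that
correction patterns gravitate toward the stereotyped relationship; the
hypothesis is stated verbally in the literature, and alternatives (e.g.
converting tilt errors into inferred task errors via 1/s) exist but are not
the default. e_a uses g evaluated at the *visual* TMD; evaluating at the
intended TMD is an equally defensible variant not taken here.

Consequences, all exercised in the tests: with λ = 0 and no noise every
update is tangent to g; pure task learning (η_a = 0) converges to full
compensation m → −30°; with η_a > 0 the steady state satisfies
η_m(m + 30) = s·η_a·(g(m + 30) − g(m)), leaving a residual error (−28.8°
for s = 0.2, η_a = η_m); pure tilt perturbations drive sign-coupled (TMD,
STA) shifts of magnitude m* = −6·s·η_a/η_m for the CCW arm; and in the
combined arms the CW tilt perturbation opposes, and the CCW one assists,
the tip-rotation compensation, delaying or accelerating the half-maximal
adaptation point.

Known limitation: the projection rule predicts that *steeper* relations
produce larger tilt-driven corrections, whereas shallow-relation
participants showing larger tilt corrections would require the opposite. An
optional slope-normalised mode (η_a divided by |g′|, `slope_normalized=True`)
captures that alternative; the tension is documented rather than resolved,
and the default remains the plain projection.

Free parameters (defaults): η_m = η_a = 0.1 (dimensionless, in [0, 1]),
λ = 0 (in [0, 0.2]), motor noise SD 1.0° in TMD and 0.2° in STA. No
published values exist for these; the learning rates are typical of
single-rate state-space models of visuomotor rotation, and noise is set so
late-phase trial-to-trial variability is of order 1°. Parameter recovery is
by grid search (default grid: η_m over 0.02–0.30 in steps of 0.01, η_a over
{0, 0.05, 0.1, 0.15, 0.2}, λ over {0, 0.02, 0.05}) minimising the squared
deviation between observed and noise-free model-predicted (TMD, STA)
series; a flat objective is flagged, not hidden.

## Synthetic study

Protocol: 360 baseline trials (each of the nine targets exactly 40 times,
shuffled within blocks of nine — whether the original randomisation was
blocked is unknown; blocking is a guess that guarantees balance), then 240
adaptation trials at the 0° target. Populations draw relation slopes from
N(0.2, 0.07²) truncated at zero — a stand-in distribution, not a published
estimate, chosen so that ±30° targets produce ≈ ±6° tilts, the calibration
that motivated the ±6° tilt perturbation. Baseline intents sit on the
participant's own relation at the nominal target ("pre-optimised"
participants: stick tilting is present from the first trial), with motor
noise added. Per-participant seeds are spawned deterministically from the
population seed; identical (config, seed) pairs give byte-identical
outputs, recorded in a run manifest with a config hash.

`run_experiment` produces measures either directly from the plane-level
states (default) or by synthesising every trial at 1 kHz and reading
measures back through the analysis chain (`kinematics=True`); the tests
show the two agree to read-out precision, so population-scale studies use
the fast path. Synthetic data emulate trial-level structure only: no
reaction times, return movements, online corrections, explicit re-aiming,
curvature, or fatigue/attention drift. Passing tests therefore validate the
pipeline's internal consistency and the learning rule's qualitative
signatures, not quantitative agreement with any human dataset; group-level
human statistics are data-dependent and are reproduced only at the level of
sign and ordering on synthetic populations. The abrupt arm (E1B) is
simulated with the same implicit rule as the gradual arm — no explicit
strategy component is modelled.

## Analysis defaults and numerical choices

Filtering: 10 Hz fourth-order Butterworth, applied forward-backward
(zero-phase) so peak-timing estimates are not lag-biased; series shorter
than 3× the filter order are rejected. TMD is the chord angle from the
trial start to the tip at the peak-velocity sample — identical to the
instantaneous velocity direction for straight paths and more robust under
noise; the instantaneous read-out is provided as an alternative. Peak
velocity takes the first index on exact ties. Movement offset is the first
sample with displacement ≥ d and speed < 5% of peak (falling back to the
last sample); no offset criterion is prescribed by the source protocol.
The nine trial segments are 1–5, 6–10, 11–15, 16–20, 21–25, 26–30, 31–120,
121–210, 211–240; the published list has trial 30 in two segments, which is
treated as a typographical overlap and normalised. Late-phase variability
is the sample SD (ddof = 1) over trials 121–240. Statistics are
paired/two-sample t, Pearson r, and Cohen's d (mean difference / SD of
differences when paired; pooled-SD otherwise); repeated-measures
ANOVA/MANOVA are deliberately not implemented.

## Problem sizes

Default simulations run at the study's own scale (240 adaptation trials,
n = 10 per arm, 20 replicates for population-level checks; 72-participant
cohorts are supported and tested for construction). Population-level test
studies run at the plane level, which is exact for these read-outs, keeping
the full suite under a minute of simulation time.
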