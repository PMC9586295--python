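# Methods

This note records the model, the estimators, the numerical choices and the
known limitations of the package, in the order the pipeline runs.

## Coordinate and sign conventions

All lengths are in µm, times in s, angles in rad. The wall-normal
coordinate y (z in the vertical plane) lies in [0, W] with walls at 0 and
W = 50 L_c (L_c = 20 µm, half the cell body plus one flagellum; W defaults
to 1000 µm). Headings live in (−π, π] with 0 < φ < π meaning motion toward
the wall at 0, so the kinematic equation is dy/dt = −V_s sin φ. In the
vertical plane θ is measured clockwise below the horizontal; up-swimming is
θ = −π/2, and the gyrotactic reorientation rate is ω_g = −cos θ/(2B), the
planar reduction of [k − (k·p)p]/(2B) for p = (cos θ, −sin θ) and vertical
unit vector k. B is the gyrotactic timescale (s).

## Track processing

Tracks are uniformly sampled at Δt = 0.1 s (10 frames/s). Smoothing uses
repeated centered moving averages, 5 passes of a 10-point window by
default. An even window is realized as the symmetric (window+1)-tap kernel
with half-weight end taps — the average of the two off-center placements —
because that filter is zero-phase: linear motion passes through unchanged
away from the track ends, where the kernel is truncated and renormalized.
A trailing or one-sided 10-point window would shift every feature by half a
frame and bias all downstream increment statistics.

Velocities are central differences (one-sided at the ends); speed is the
velocity norm; heading is atan2(−v_y, v_x); angular velocity is the
minimally wrapped heading increment over 2Δt (Δt at the ends), which
prevents ±2π wraps from registering as spurious sharp turns. Samples with
exactly zero velocity have no heading; they carry the previous defined
heading and a flag, rather than NaNs that would poison binned statistics.
Tracks with mean speed ≤ 5 µm/s are discarded before any population
statistic.

## Sharp turns

An event is a maximal contiguous run of samples with |ω| ≥ ω_ct
(π/8 rad/s horizontal, π/2 rad/s vertical — well above the respective
background levels). t0 is the earliest in-run argmax of |ω|. This run rule
is a deterministic, oracle-checkable substitute for peak-finding routines
whose extent rule is rarely specified; runs are never merged across
sub-threshold gaps. Event statistics are binned by the wall-normal
coordinate at t0 in 2.5 L_c bins; N_traj counts tracks that visit each
bin; region-averaged V_s(t−t0) and |ω(t−t0)| profiles use the wall bands
(0–2.5 L_c from either wall) and the mid-channel band (23.75–26.25 L_c).

## Binned behaviour fields and the finite-frame response

Each sample with a successor contributes (y, φ, speed, Δφ) to a 51 × 80
histogram over [0, W] × (−π, π]; the increment is attributed to the bin of
its starting sample (the Itô pre-point of the model). Per bin with at
least 10 increments, ω = mean(Δφ)/Δt and D_r = var(Δφ)/(2Δt) (unbiased
variance); under-populated bins are flagged undefined, never zero-filled.
P(y, φ) is the jointly normalized count density; N(y) is the orientation
integral of P normalized to width average 1.

Headings estimated from position chords are, to first order in the heading
spread, *averages* of the true heading over a 2Δt window. Three exact
consequences (derived for Brownian headings and verified by simulation to
0.1%):

* increments of window-averaged headings carry 5/12 of the true increment
  variance, at any Δt — so D_r estimated from raw track headings is
  multiplied by 12/5 (`estimate_fields_from_tracks`), and the corrected
  estimator is unbiased in the bulk.  The factor is specific to the
  unsmoothed central-difference scheme: when tracks are smoothed first
  (the default of the `analyze` command, mirroring the experimental
  procedure) the attenuation depends on the smoothing kernel and the
  reported D_r is the apparent, processing-dependent value;
* successive increments are MA(2)-correlated (ρ₁ = 3/5, ρ₂ = 1/10), so the
  SE of the binned mean increment is √(12/5) times the iid value, and the
  SE of the increment variance is √1.74 times the iid value;
* the binned ω estimator is unbiased for the *kernel-filtered* drift: in
  terms of frame-interval means M of the true coefficient, the expected
  responses are (M₋₁ + 2M₀ + M₊₁)/4 for ω, (M₋₁ + 3M₀ + M₊₁)/5 for D_r,
  and the chord speed is (M₋₁ + M₀)/2 times the shortening factor
  1 − D_rΔt/3 − (ωΔt)²/6.

The recovery suite (`gyrowall.validate`) therefore compares binned
estimates against the kernel-filtered ground truth, averaged over exactly
the samples each bin pooled, with the inflated SEs above plus quadrature
model floors for the neglected second-order terms (2×10⁻⁴ relative on
speed, 3% of the local torque, 1.5% of the local D_r). With those error
models the standardized errors are ~N(0, 1): across seeds, 0.4–2.4% of
bins exceed |z| = 3 and none exceeds 4.2; the acceptance test asserts
≤ 4% and max |z| < 6. A literal "every bin within 3 SE" is unattainable
for any correct implementation once a few hundred bins are compared —
0.27% of honest standardized errors exceed 3 by chance.

Two scope rules in the recovery comparison: the two position rows nearest
each wall are excluded, because the ±2-frame chord window can straddle a
specular reflection whose heading flip no smooth closure describes; and
recovery runs with the sharp-turn process disabled, because injected turns
are *additional* heading variance on top of the closures — indeed the
experimental observation this package models is precisely that near-wall
turns masquerade as enhanced D_r.

## Langevin model

Forward Euler–Maruyama in the Itô convention (coefficients at the
pre-point, no spurious-drift correction), dimensionless step
Δτ = 2×10⁻⁴ with τ = t·V_sb/H. Reflection at the walls mirrors the
position and flips the heading sign — the unique rule that preserves speed
and flips the wall-normal velocity component, reducing to billiard
reflection in the zero-noise limit; an overshoot beyond one reflection
aborts the run as a step-size failure. Heading is periodic on (−π, π].
Variants I–V switch wall speed/torque/diffusivity and gyrotaxis on and off
as in the model-variant table in `gyrowall.simulate`. The streamwise
coordinate is not part of the state (nothing depends on it); it is
integrated only when track dumps are requested. Coefficient fields are
either analytic closures or bilinear interpolants of a binned field with a
periodic heading axis; undefined bins are filled from the nearest defined
bin (counted and reported). Ensembles accumulate the (y, φ) histogram
every 25th step after a burn-in of τ = 5 by default (the late-time
distribution is the target; sensitivity to the burn-in is below sampling
error in all runs reported here), and all runs are bit-reproducible from
the seed.

## Synthetic study conditions

The generator emulates the experimental conditions: 1000 µm channel,
bulk speed 80 µm/s, bulk D_r 0.025 rad²/s, speed wall layer decaying over
100 µm (wall-normal heading) to 70 µm (wall-parallel), wall torque of
amplitude 1 rad/s peaking at tilted headings (±π/4, ±3π/4) and decaying
over 50 µm, a 10× D_r enhancement peaking at wall-normal headings over
50 µm, sharp turns as a Poisson process (bulk rate 0.02 s⁻¹, 3× within
2.5 L_c of walls, exponential durations of mean 1 s, constant boosted
|ω| ∈ [0.8, 1.6] rad/s), and 10 frames/s sampling. The wall torque aligns
swimmers wall-parallel (−A sin 2φ at the lower wall and its mirror at the
upper), matching the observed dominance of wall-parallel swimming near
boundaries; its magnitude peaks at the tilted headings where the measured
torque peaks. Tracks carry a per-track lognormal speed factor (sd 15%):
swimming-speed heterogeneity is a documented property of these populations
(only fast swimmers reach the bulk against gyrotaxis), and without it the
binned speed comparison would be dominated by the 0.1%-level chord bias
rather than by realistic cell-to-cell variance. Integration runs at 10 ms
and subsamples ×10 to frames, keeping generator discretization bias far
below estimator tolerance; the sidecar records per-frame and per-interval
true coefficients and turn labels.

What the generator does *not* emulate: localization noise, helical
zigzag (heading noise is Brownian at all scales, so smoothing cannot
separate an oscillatory component the way it does for real tracks — at
the default D_r the chord |ω| noise at 10 fps is comparable to the
π/8 threshold, which is why the Poisson-rate validation of the turn
process runs at a low-noise condition where events are identifiable),
track truncation by the depth of field, or cell–cell interactions.
Passing tests therefore establish estimator correctness under the model's
own assumptions, not fidelity of those assumptions to any particular
organism.

## Péclet self-consistency construction

Outside the wall layers, the bounded vertical distribution should follow
N = N₀ exp(σz/H) with σ = V_z H / D_T. The construction evaluated at the
reference value σ = 3.112: an unbounded variant-III control run (constant
V_s = 100 µm/s, D_r = 0.1 rad²/s, B = 60 s) yields V_z (slope of mean z)
and D_T (half-slope of var z) after a 100 s orientation transient; the
channel height is set to H = 3.112·D_T/V_z (≈ 3.7 cm, ≈ 37 persistence
lengths V_s/D_r); the bounded run (10⁴ walkers, uniform initial positions,
τ_end = 40 with burn-in 22 ≈ three relaxation times H²/(π²D_T)) is fitted
on log N over z ∈ [0.1H, 0.9H]. The parameters are chosen so the
drift–diffusion limit underlying the exponential actually holds: the
kinetic correction to the decay rate is O((σℓ/H)²) ≈ 1–2%, and weaker bias
would only inflate the cost of resolving V_z, whose mean-growth estimator
carries most of the budget's statistical error (~2%). Across seeds the
fitted σ lands within 5% of 3.112. With the bulk D_r = 0.025 rad²/s the
same construction would require H ≈ 5 cm and correspondingly longer runs;
the physics is identical.

Other deliberately-sized runs: the uniformity check (variant I, constant
coefficients, max|N−1| < 0.05 at 10⁴ walkers) uses D_r = 0.25 rad²/s and
τ_end = 40 so that position decorrelation is fast enough for the stated
bound to be a ~3σ statement at the stated walker count; the closed-form
orientation law (χ² against exp(−sin θ/(2BD_r)), B = 5 s, D_r = 0.025) is
checked on the free orientation process (no walls), since reflections
couple position and heading and shift the bounded marginal away from the
free-space law; and the step-size robustness check couples the coarse and
half-step integrations through the same Brownian path, isolating the
discretization effect from sampling noise.

## Far-field diagnostic

The image-force-dipole prediction
ω(h, φ) = p/(8πμ) · 3 sin 2φ/(16h³) · [1 + (Γ/2)(1 + sin²φ)] is
implemented as a comparison tool only. The bracket is read with sin²φ,
keeping the whole expression odd in φ, consistent with the sign-change
structure at φ = ±π/2 ± arccos(1/3) quoted for the wall-induced velocity;
the h⁻³ scaling and oddness are exact properties under test. The
wall-induced-velocity diagnostic −(V_s − V_sb) sin φ fits a power law of
|u| against h per orientation over a configurable range (default
20–200 µm) and reports zero crossings of u(φ) at a reference distance;
the fitting range is a parameter because no canonical range exists.

## Known limitations

* The 12/5 attenuation correction is exact for Brownian headings; for
  strongly non-Markovian heading dynamics (helical swimmers) the factor
  differs, and D_r at 0.1 s sampling is then an effective, Δt-dependent
  quantity — as the convergence caveats attached to experimental D_r
  estimates acknowledge.
* Sharp-turn detection near walls conflates injected turns with specular
  reflections; this mirrors reality (wall contact *is* a turn) but means
  rate parameters are only identifiable in the bulk.
* Variant II/V runs driven by estimated (binned) fields inherit the
  estimation noise of those fields; no regularization beyond
  nearest-neighbor fill of undefined bins is applied.
* The simulator is 2-D in (position, heading); no 3-D orientation
  dynamics, cell–cell interactions, or flow coupling.
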