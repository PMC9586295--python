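# gyrowall

Trajectory statistics and individual-based modelling of gyrotactic
microswimmers near plane walls.

Swimming algae such as *Heterosigma akashiwo* accumulate near solid
boundaries. Two ingredients drive this: **gyrotaxis** — the balance of
gravitational and viscous torques that biases cells toward up-swimming at a
rate ω_g = −cos θ/(2B) — and **cell–wall interaction**, which near a wall
raises the probability of *sharp turns* (episodes with |ω| above a critical
value ω_ct), lowers the swimming speed V_s, applies an effective wall torque
ω_w, and enhances the rotational diffusivity D_r by an order of magnitude.
This package implements the full computational chain used to quantify and
model that behaviour:

1. **Track analysis** — planar track tables (TRACK_ID, POSITION_T,
   POSITION_X, POSITION_Y; 10 frames/s) are smoothed (5 passes of a
   10-point window), converted to per-sample speed, heading φ ∈ (−π, π] and
   angular velocity by central differences, and screened by a 5 µm/s mean
   speed filter.
2. **Sharp-turn statistics** — events are maximal runs with |ω| ≥ ω_ct
   (π/8 rad/s in the horizontal plane, π/2 rad/s in the vertical plane),
   with per-event duration T_t, peak |ω|, and wall-distance-binned
   N_t/N_traj profiles.
3. **Behaviour fields** — heading increments Δφ are histogrammed on a
   51 × 80 (position × orientation) grid; per bin,
   ω = mean(Δφ)/Δt and D_r = var(Δφ)/(2Δt), plus the joint PDF P(y, φ) and
   the normalized concentration N(y) (width average 1). Because headings
   come from position chords, the raw increment variance carries exactly
   5/12 of the true heading-increment variance; the pipeline applies the
   closed-form 12/5 correction (see `docs/methods.md`).
4. **Langevin model** — the Itô system

       dy = −V_s(y, φ) sin φ dt
       dφ = [ω_w(y, φ) + ω_g(φ)] dt + √(2 D_r(y, φ)) dW

   integrated by forward Euler (Δτ = 2×10⁻⁴, τ = t·V_sb/H) with specular
   reflecting walls and periodic heading, in five variants (I–V) that
   switch the wall-speed, wall-torque, gyrotaxis and wall-diffusivity
   terms on and off.
5. **Synthetic data** — a generator producing track sets with known
   coefficient closures, wall layers, sharp-turn injection and gyrotactic
   bias, so every estimator is testable by parameter recovery.

## Worked example

```python
import numpy as np
from gyrowall import SyntheticSpec, pooled_drift_diffusion
from gyrowall.synth import make_fields, generate_tracks
from gyrowall.fields import estimate_fields_from_tracks

spec = SyntheticSpec(seed=1)               # 1000 um channel, D_rb = 0.025
tracks, truth = generate_tracks(make_fields(spec), spec,
                                n_tracks=400, duration=60.0, turns=False)
grid = estimate_fields_from_tracks(tracks)
print(f"bulk D_r = {np.nanmean(grid.D_r[10:41]):.4f} rad^2/s")
```

prints

```
bulk D_r = 0.0256 rad^2/s
```

— the binned moment estimator recovers the generating bulk rotational
diffusivity (0.025 rad²/s) from the tracks alone; the ~2% excess here is
within the sampling error of a 400-track set. The numbered drivers under
`analysis/` run the full narrative: `01` generates the synthetic dataset,
`02` computes sharp-turn statistics (near-wall turn probability exceeds
the bulk by the injected factor plus wall collisions), `03` performs the
bin-by-bin parameter recovery, `04` compares the concentration profiles of
model variants I–V, and `05` recovers the gyrotactic timescale B and the
Péclet-number self-consistency of the vertical concentration profile
N = N₀ exp(σz/H), σ = V_z H / D_T.

The command-line interface exposes the same pipeline on files:

```bash
gyrowall synth -o data --n-tracks 100 --duration 30 --seed 1
gyrowall analyze data/tracks.tsv -o out
gyrowall simulate --variant III -o sim --seed 2 --n-traj 10000
gyrowall fit-sigma sim/concentration.tsv -H 1000
```

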