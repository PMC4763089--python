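# rheopipe

Analysis pipeline for **rheotaxis of larval zebrafish in a radial suction
flow** — the behavior by which fish turn into an oncoming current and swim
to hold position. In the assay this package models, a suction needle in
shallow water (depth *h*) draws larvae toward it; the depth-averaged flow is
a point sink with radial speed *q*/ρ, where *q = Q\_v /(2πh)* is the
surfacic flow rate and ρ the distance to the suction point. High-speed
video (250 Hz, 35 µm/pixel, 22 × 18 mm field of view) of bright larvae on a
dark background is reduced to posture, swim bouts and population statistics.

It is written for behavioral neuroscientists and quantitative ethologists
who need the full measurement chain — and a ground-truthed synthetic assay
to validate it against, since every stage can be run on simulated sessions
whose true poses, bout schedules and phase labels are known.

## What it computes

1. **Segmentation** — background subtraction (run average, or a robust
   low-percentile variant), Gaussian smoothing (175 µm box, σ = 50 µm),
   thresholding, 4-connected components, 500 px size filter.
2. **Posture** — equivalent ellipses from intensity-weighted image moments;
   a level-1 BSP split into head and tail halves; body angle α between the
   head axis and the **outward** radial direction (α = 0 ⇔ counterflow);
   signed curvature κ = ±1/R from the intersection of the two halves' minor
   axes (positive when the center of curvature lies right of the head).
3. **Tracking** — Crocker–Grier-style linking (optimal assignment, 3.5 mm
   gate, 100-frame memory) and automatic track curation.
4. **Bouts** — swim bouts from the curvature trace (σ of κ̇ over 20 ms,
   normalized by a 400 ms sub-median baseline, threshold 5 for > 40 ms);
   tail beats as |relative κ| > 0.1 excursions; per-bout kinematics by
   fitting the Stokes-drag impulse response

       ρ(t_k + Δ) = ρ_k + λ u cos(α) (1 − e^(−Δ/λ)) − v_f Δ

   for the impulse speed *u* and damping time λ, with the fluid speed
   *v\_f* from an affine pre-bout fit.
5. **Passive baseline** — the Jeffery-type reorientation ODE
   α̇ = *qL*/ρ · sin α coupled to ρ̇ = −*q*/ρ (sign, ρ-exponent and frozen-ρ
   variants exposed), for inert-larva comparison curves.
6. **Statistics** — circular variance (1 − |mean resultant|), automated
   counterflow-swim-sequence (CSS) labeling, onset-aligned circular-variance
   curves, fixed-bandwidth Gaussian KDEs, Kolmogorov–Smirnov and Welch
   tests, radial position-holding profiles (δ vs ρ), CSS-onset summaries
   (ρ₁, v₁ per flow rate or age), and the egocentric density of the suction
   point.
7. **Synthetic assay** — `simulate_session` generates exploration
   (random-heading bouts) followed by CSS triggered at a programmed radius,
   with position-holding bout pacing and exponential-impulse kinematics;
   `render_frames` draws the larvae as bent bright rods and produces
   multi-page TIFF stacks with ground-truth CSV tables.

See `docs/methods.md` for the model details and `docs/UNITS.md` for units.

## Worked example

Simulate a 10 s session at 0.22 mL/s, render and re-measure it, and extract
the counterflow statistics:

```python
import numpy as np
from rheopipe import FlowConfig, PipelineConfig, flow_speed
from rheopipe import pipeline as pl, synthdata as sd
from rheopipe.stats import circular_variance, label_css

cfg = PipelineConfig(flow=FlowConfig(Q_v=220.0))          # 0.22 mL/s suction
print(f"fluid speed at rho = 8.75 mm: {flow_speed(8.75, cfg.flow):.3f} mm/s")

truth = sd.simulate_session(
    cfg.flow, cfg.larva, cfg.behavior, n_larvae=2, duration=10.0, seed=7,
    init_positions=[(8.5, 6.5), (-8.5, -6.5)],
)
bg = pl.session_background(truth, cfg)
per_frame = pl.analyze_frames(sd.iter_frames(truth, cfg.noise, seed=7),
                              cfg, background=bg)
tracks = pl.tracks_from_poses(per_frame, cfg)
series = pl.series_from_tracks(tracks, cfg)
for s in series:
    onset = s.bouts[label_css(s).onset]
    post = [b.alpha_offset for b in s.bouts if b.t_k >= onset.t_k]
    print(f"larva {s.larva_id}: {len(s.bouts)} bouts, CSS onset at "
          f"t = {onset.t_k:.2f} s, rho_1 = {onset.rho_k:.2f} mm, "
          f"v_f = {onset.v_f:.2f} mm/s")
    print(f"  circular variance of alpha after onset: "
          f"{circular_variance(post):.3f}")
```

prints (exactly, given the seed):

```
fluid speed at rho = 8.75 mm: 1.000 mm/s
larva 0: 17 bouts, CSS onset at t = 2.40 s, rho_1 = 7.76 mm, v_f = 1.04 mm/s
  circular variance of alpha after onset: 0.011
larva 1: 11 bouts, CSS onset at t = 2.99 s, rho_1 = 7.85 mm, v_f = 0.96 mm/s
  circular variance of alpha after onset: 0.013
```

Both larvae, programmed to start counterflow swimming at 8 mm, are detected
(through rendered video, not ground truth) with onset radii within a
reaction-delay drift of 8 mm; the fitted pre-bout fluid speed ≈ 1 mm/s
matches *q*/ρ₁; and the near-zero circular variance of the post-onset body
angles quantifies their alignment against the flow.

The same chain is available from a shell:

```sh
rheopipe run --config config.json --seed 7 --out runs/demo
rheopipe passive --init init.csv --out traj.csv     # inert-larva baseline
```

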