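# dispersr

Movement-ecology analysis of GPS-collared dispersers: track cleaning,
dispersal-phase classification, compass directionality, and
integrated step-selection functions (iSSF) testing whether wide
roads and large waterbodies act as movement boundaries.  Built for
range-edge dispersal studies of mesocarnivores (raccoon dogs are the
motivating species), where the interesting individuals make km-scale
directed movements between periods of residency, and where the field
data are often access-restricted — so the package includes a
two-state track simulator with known ground truth that every
statistical component is validated against.

## What it computes

**Cleaning** (`dispersr.tracks`): Movebank-style CSV in; per
individual, end-trimming, iterative removal of fixes implying speeds
strictly above 40 kmph, splitting at gaps strictly over 7 days, and
linear-interpolation resampling to a regular 3-h grid (interpolated
fixes flagged).  Displacement, total distance, per-month distance,
Welch's t.

**Phases** (`dispersr.phases`): net squared displacement series,
position semivariograms, a stationary/travel step threshold from the
density minimum between the two modes of a Gaussian KDE of
ln(step speed) (fallback 200 m), and an explicit dispersal-bout rule
(travel runs with ≥ 3 steps and ≥ 5 km net displacement).

**Directionality** (`dispersr.direction`): dispersal-step headings
binned into eight 45° compass sectors; per-sector one-vs-rest
Spearman correlations across individuals, plus the full pairwise
matrix.

**Boundaries** (`dispersr.landscape`, `dispersr.issf`): barrier
filtering (roads > 3 m, rivers > 5 m, lakes > 22 500 ha), Euclidean
distance rasters (cell 100 m, ESRI ASCII I/O), and per-individual
iSSF: each used dispersal step vs K = 40 random steps drawn from a
tentative gamma/von Mises kernel fitted to that individual, scored by
conditional logistic regression on the stratified partial likelihood

    L(β) = ∏ₛ exp(βᵀx_used,s) / Σ_{j∈s} exp(βᵀx_j,s)

with the 11-term design {sl, ln sl, cos ta, road_end, water_end, and
the six movement × start-distance interactions}, Newton–Raphson with
analytic Hessian, Wald inference, and Table-style population
summaries (mean ± SD of coef/SE/OR, count significant at α = 0.05).

**Simulation** (`dispersr.simulate`): random barrier landscapes and
two-state (stationary/dispersal) Markov tracks with per-state
movement kernels and optional exponential selection on
distance-to-boundary at candidate end points — the ground truth for
the validation experiments in `dispersr.validation`.

## Worked example

Simulate one disperser with a known attraction *away* from water
(β_water = +5·10⁻⁴ per meter of distance), clean it, classify phases
and fit its iSSF:

```python
import numpy as np
import dispersr as d

cfg  = d.SimulationConfig(seed=42, n_steps=400, beta_water_end=5e-4)
land = d.make_landscape(cfg)
sim  = d.simulate_track(cfg, land, rng=np.random.default_rng(42))

track, report = d.process_track(sim.track, d.FilterConfig())
print(f"displacement: {d.displacement(track)/1000:.1f} km, "
      f"total: {d.total_distance(track)/1000:.1f} km")

thr = d.kde_step_threshold(track.steps)
lab = d.segment_bouts(d.classify_steps(track.steps, thr), track.steps)
print(d.phase_summaries(track.steps, lab).round(2).to_string(index=False))

kern   = d.fit_kernel(track.steps)
strata = d.generate_random_steps(track.steps, lab, kern, K=40,
                                 rng=np.random.default_rng(7),
                                 extent=land.extent)
design = d.build_design_matrix(strata, land.road_raster, land.water_raster)
fit    = d.fit_conditional_logit(design)
print(fit.summary().loc[["water_end", "road_end"]].round(5))
```

Output:

```
displacement: 30.4 km, total: 430.8 km
     phase  distance_m  duration_h  mean_speed_kmph  n_steps
stationary   266487.99       972.0             0.27      324
 dispersal   164343.16       210.0             0.78       70
              coef       se       or        z        p
water_end  0.00036  0.00009  1.00036  4.14416  0.00003
road_end   0.00007  0.00009  1.00007  0.79617  0.42594
```

Reading it: the animal covered 431 km of path for 30 km of net
displacement; the KDE threshold (263 m here) splits its steps into a
slow residency phase (0.27 kmph) and a fast dispersal phase
(0.78 kmph).  The fitted water_end coefficient is positive and
significant — each extra meter of distance from water multiplies a
candidate step's relative selection odds by 1.00036, i.e. the animal
prefers end points away from water, as simulated — while road_end,
which had no selection in the generator, is correctly indistinguishable
from zero.

## Command line

The same chain runs from a shell, stage by stage or end to end, from
one YAML config and one seed; outputs are plain CSV stamped with the
config hash and seed, and reruns are byte-identical:

```sh
dispersr all --config study.yaml --seed 9 --out results/
# or: dispersr simulate / preprocess / classify / direction / issf / report
```

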