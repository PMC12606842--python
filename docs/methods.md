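# Methods

`dispersr` implements a complete movement-ecology analysis chain for
GPS-collared mesocarnivores (its motivating system is raccoon-dog
dispersal at a range edge): track cleaning, dispersal-phase
classification, compass directionality, and integrated step-selection
functions (iSSF) asking whether linear landscape features — wide
roads and large waterbodies — act as movement boundaries.  Because
field relocation data of this kind are usually access-restricted, the
package ships a two-state track simulator with known ground truth;
every statistical claim the package makes is validated against that
generator.

## Track model and cleaning

A track is an ordered series of fixes `(t, x, y)` for one individual
in a planar projected CRS (meters; x east, y north).  Steps join
consecutive fixes; headings are degrees clockwise from north in
[0, 360), turn angles the signed heading change wrapped to
(−180, 180].  Cleaning applies, in order:

1. **Trim** — the first and last `trim_steps` fixes (default 3) are
   dropped: fixes recorded around collaring and collar retrieval do
   not represent free movement.  Optionally the whole first 24 h is
   dropped when it covers more fixes than the step trim.
2. **Speed filter** — while any step is strictly faster than
   `max_speed_kmph` (default 40, above the species' plausible
   sustained speed), the end fix of the fastest offending step is
   removed and steps are rebuilt.  Removing a fix rather than a step
   keeps the track connected; iteration handles the two spurious
   steps a single bad fix creates.
3. **Gap split** — steps spanning strictly more than `max_gap_days`
   (default 7; transmitters go quiet during winter sleep) are deleted
   and the track is split into segments there.  No step or turn angle
   ever crosses a declared gap.
4. **Regularization** — each segment is resampled onto a regular grid
   (default 3 h) anchored at the segment's first fix, with positions
   linearly interpolated between bracketing raw fixes and interpolated
   fixes flagged `imputed`.  Linear interpolation was chosen over a
   continuous-time movement model deliberately: it is deterministic,
   testable, and adequate at a 3-h resolution relative to the
   hundreds-of-meters step scale; the imputation flag lets any
   downstream consumer quantify its exposure.

All gap/speed thresholds are strict inequalities.  Timestamps are
normalized to UTC; duplicate timestamps keep the first fix.  Lon/lat
input is projected at read time with a local equirectangular
projection about the data centroid — over study extents of a few
hundred kilometers the distortion is far below the GPS error and cell
size; for continental extents supply projected coordinates instead.

## Dispersal-phase classification

Net squared displacement (NSD, squared distance of each fix from the
track origin) and position semivariograms
(γ(τ) = ½·E‖z(t+τ) − z(t)‖², pooled over the two axes) are provided
as diagnostics: NSD ramps during dispersal and plateaus during
residency; the semivariogram of a range-resident animal saturates
while that of a disperser keeps climbing.

Step states are classified by a data-driven threshold: a Gaussian KDE
(Silverman bandwidth, 512-point grid over the data range) of
ln(step speed) is typically bimodal for animals alternating between
residency and travel; the step length corresponding to the density
minimum strictly between the two dominant modes (modes below 5% of
the peak density are ignored as spurious micro-modes) separates
*stationary* (length ≤ τ) from *travel* steps.  Length and speed are
interchangeable after regularization; the threshold is reported as a
length.  When no second mode survives, the classifier falls back to
τ = 200 m (flagged), a conservative default an order of magnitude
below the travel-step scale.

Dispersal *bouts* are defined by an explicit rule rather than visual
NSD inspection: a maximal within-segment run of travel steps is a
dispersal bout iff it has at least `min_run` steps (default 3) and a
net displacement of at least `min_net_m` (default 5000 m).  The two
conditions separate directed km-scale movement from foraging loops,
which are travel-speed but closed.  Disqualified runs are relabeled
stationary.  The rule is deterministic and idempotent.

## Directionality

Dispersal-step headings are binned into eight 45° compass sectors,
left-closed from due north.  Per-sector preference across the
population is tested by the Spearman rank correlation between one
sector's per-individual counts and the summed counts of the other
seven; a sector counts as preferred only at p < 0.05.  This
one-vs-rest construction is calibrated for a neutrality model in
which each individual's per-sector counts are independent (Poisson)
draws; under a fixed-total (multinomial) model the statistic is
degenerate by construction (the rest is the complement of the
sector), so totals must carry no direction information — which is
exactly what neutrality means here.  The full 8×8 pairwise matrix is
also reported.

## Movement boundaries and the iSSF

Features below a size that plausibly impedes movement are filtered
out first: roads ≤ 3 m wide, rivers ≤ 5 m wide, lakes ≤ 22 500 ha
(all strict; all configurable).  Rivers and lakes form a single
*waterbody* class, roads the other.  For each class a distance raster
(default cell 100 m) stores the exact Euclidean distance from each
cell center to the nearest retained feature, so the raster is within
cell·√2/2 of the true distance anywhere; covariates are sampled by
bilinear interpolation between cell centers for smoothness.  The
raster extent must cover every step end point with margin.

The iSSF follows the standard used-versus-available design.  Per
individual, a tentative movement kernel — gamma step lengths, von
Mises turn angles, the pairing implied by the step-length /
log-step-length / cosine-turn-angle adjustment terms — is fitted to
the observed dispersal steps (gamma by full MLE, von Mises by
circular-mean plus A(κ) inversion with two Newton refinements).  Each
used dispersal step with a defined turn angle is matched with K = 40
random steps sharing its start fix, lengths from the gamma fit and
headings from the previous absolute heading plus a von Mises turn.
The design has 11 terms: `sl`, `log_sl`, `cos_ta`, the end-point
distances `road_end` and `water_end`, and the six interactions of the
three movement terms with the start-point distances (movement is
allowed to change near a boundary).  Start-distance main effects are
constant within a stratum, carry no conditional-likelihood
information, and are never included; any other column that turns out
stratum-constant is flagged inestimable and reported as NaN.

Coefficients maximize the stratified partial likelihood
L(β) = Π_s exp(βᵀx_used,s) / Σ_{j∈s} exp(βᵀx_j,s)
by Newton–Raphson with analytic gradient and Hessian, step-halving,
and convergence at a relative log-likelihood change below 1e-9 (max
100 iterations).  Columns are standardized internally for
conditioning and the fit is expressed on the original scale.
Standard errors come from the inverse observed information; inference
is two-sided Wald, α = 0.05.  Complete separation is detected as a
diverging coefficient norm and reported as non-convergence rather
than a spurious estimate.  Population summaries report the mean ± SD
of coefficient, SE, and odds ratio across converged individual fits
plus the count of individuals significant per term; end-point
distances are additionally summarized by start-distance bin (all,
< 500 m, < 100 m), identically for observed and random steps.

## The synthetic generator

`simulate` produces a barrier landscape (straight extent-crossing
roads 4–10 m wide, wiggly rivers 6–30 m wide, convex-polygon lakes
with areas straddling the 22 500 ha filter threshold) and two-state
tracks: a stationary/dispersal Markov chain (persistence 0.9) over
per-state kernels, by default gamma mean 100 m with uniform turns
(stationary) and gamma mean 2500 m with κ = 1 directional persistence
(dispersal) at a 3-h fix cadence — putting the two states on the
residency and travel scales the classifier assumes, with the
dispersal scale near the ~1 kmph phase speed reported for dispersing
raccoon dogs.  At each step C = 50 candidate (length, turn) pairs are
drawn and one is selected with probability ∝
exp(β_road·d_road + β_water·d_water) at the candidate end point; zero
betas reduce to kernel-only movement.  C is deliberately independent
of the analysis-side K to avoid circularity.  Candidates leaving the
study area are resampled (reflective boundary).  Telemetry defects —
speed-outlier fixes, multi-day gaps, irregular 2–4 h cadence — can be
injected to exercise the cleaning chain.

What the generator does *not* emulate: habitat preference beyond the
two distance covariates, seasonality, ice cover, home-range
attraction, social effects, and GPS position noise below the outlier
scale.  Passing tests therefore demonstrate estimator correctness
under the stated movement model, not robustness to every field
complication.

## Validation experiments and their sizes

The `validation` module runs the estimator end-to-end against the
generator.  Two geometric details matter and were found the hard way:

- **Raster margin.**  Analysis rasters extend 20 km beyond the
  simulated study area.  If they stopped at its boundary, random
  steps would be rejection-truncated against that boundary a second
  time (the tentative kernel is already fitted to boundary-truncated
  observed steps), biasing random steps short relative to used steps.
- **Study-area size.**  Validation populations disperse on a 200-km
  square: 300 persistent ~2.5-km steps travel 60–70 km, and on a
  small box the tracks hug the reflective edge, deflecting observed
  steps in a way i.i.d. random steps cannot match.  The box is sized
  to the track scale; barrier counts scale with it to keep feature
  density comparable.

The standard experiment simulates replicate populations of 20
dispersing individuals × 300 dispersal steps.  With
β_water = +5·10⁻⁴ per m the per-individual estimates recover the
coefficient essentially unbiasedly; 95% Wald intervals cover truth
slightly below nominal (≈93% over 2000 fits) because the K = 40
random-step sample and the shared kernel fit add Monte Carlo
variability the model-based information matrix does not see — a
sandwich estimator was tried and does not close the gap, since the
extra variability sits inside each stratum, not between strata.  With
all betas zero, per-term Wald false-positive rates sit at the nominal
5% and observed-vs-random distance-bin means agree within sampling
error, reproducing the no-boundary-effect pattern as a calibration
property.  These sizes keep the full validation suite within minutes
on one core.

## Known limitations

- Linear-interpolation imputation underestimates tortuosity between
  distant raw fixes; imputation fractions are reported so users can
  filter.
- The KDE threshold assumes a shared within-individual speed mixture;
  individuals that never disperse fall back to the fixed 200 m
  threshold.
- The bout rule's `min_net_m` default (5 km) is tuned to km-scale
  dispersal; very slow dispersers would need a lower value.
- Per-individual fitting with ~tens of true steps (as in the
  motivating data) yields wide intervals; the package deliberately
  offers no pooled or mixed-effects iSSF.
- Wald coverage is mildly anticonservative (see above); treat
  borderline per-individual significance with caution.
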