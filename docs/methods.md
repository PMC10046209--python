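# Methods

This note documents the models behind `figground`: what is simulated,
which knobs matter, the numerical choices, and what the simulations can
and cannot say about real data.

## Coordinate and timing conventions

All geometry is in degrees of visual angle with fixation at the origin,
x rightward and y upward; peripheral stimuli sit to the right of
fixation at (eccentricity, 0). Clips run at 30 fps for 1 s — the
duration of one gait cycle, shared by all three tasks so that task
difficulty is not confounded with viewing time. Both values are
configurable (`WalkerParams.fps`, `gait_period`,
`GroupingParams.duration`).

## The parametric walker

The motion-capture walkers the experimental literature uses are not
redistributable, so the walker here is a parametric stand-in: 13 joints
in walker-centred 3-D coordinates (lateral, vertical, forward), each
following a mean position plus one or two sinusoidal harmonics of the
gait cycle. Right-side joints are derived from the left by mirroring
the lateral mean and advancing every order-k harmonic by k·π, which
enforces exact bilateral antiphase (half-gait-period shift) by
construction. The default coefficient table (`DEFAULT_GAIT_TABLE`)
encodes pendular arm/leg swing at the stride frequency, arm–leg
counter-rotation, and double-frequency trunk bob; it is a plausible
gait, not a fit to any recorded subject, and tests deliberately assert
structure (13 joints, periodicity, antiphase, calibrated speed) rather
than coefficients.

The 3-D gait is orthographically projected at one of the five
experimental azimuths; ±90° are profile views, 0° frontal. A single
kinematic gain on all oscillation amplitudes is calibrated so the mean
per-dot frame-to-frame speed in *profile* view equals `speed_target`
(default 9.5 deg/s at the 16-deg reference height). Walking in place
makes that speed exactly linear in the gain, so the calibration is a
closed-form ratio (a bisection to 0.1 % is used only for the optional
translating walker, where the relation is merely monotone). Oblique and
frontal projections are slower than profile views, as real orthographic
projections are; which azimuth the published 9.5 deg/s refers to is not
stated, and profile was chosen as the canonical view.

Scrambling keeps each dot's frame-to-frame displacement sequence,
negates its vertical component (the upside-down walker), and restarts
each dot at a uniform position in the figure bounding box. This
preserves the per-dot speed profile exactly — the speed multiset of a
scrambled clip equals the original's to machine precision — while
destroying the global body form.

## Grouping stimuli

The static stimulus places 12 equal dots on an n×(12/n) grid (n = 3 or
4 columns) spanning 80 % of the bounding box; the scrambled control
draws 12 uniform positions over the same box and resamples (at most
100 times) until the column-alignment score falls below the detection
criterion, so a "scrambled" stimulus can never accidentally be
column-grouped. The dynamic stimulus translates the three-column grid
rigidly at 9.5 deg/s in one of four directions; its control moves each
dot at the same speed in an independent uniform direction. Grouped and
scrambled variants of a condition share bounding box and dot diameter
exactly.

## Visual noise

Noise dots share the diameter and the motion statistics of the task's
scrambled control: static noise is stationary, dynamic noise moves at
the stimulus speed in independent random directions, and walker noise
trajectories are drawn with replacement from the 13 inverted-walker
displacement sequences. Noise starts are uniform over the bounding box
expanded linearly by `area_factor` (default 1.5 — the noise overlaps
the figure and extends half a stimulus beyond it; the experimental
description says only "a larger area"). Embedding never touches figure
dots, and magnification commutes with embedding under a shared seed.

## Eccentric placement

Admissible (eccentricity, size) pairs follow the study's size table
(0°: 4/8/16; 15°: 8/16/20; 30°: 16/20/30/40 deg). Generators produce
reference-size (16 deg) geometry; `scale_to_layout` multiplies
positions, diameters and hence speeds by size/16 and recentres the
stimulus at (eccentricity, 0). Whether dot speed rescaled with
magnification in the original display is unstated; proportional
scaling was chosen because the procedure scaled "each dot and the
distance between the dots" proportionately.

## The staircase

`run_staircase` implements the block-up-and-down rules: blocks of four
trials, up only on a fully correct block; start at 0 with a first jump
to 20; step 20 → 10 after two reversals, → 5 after two more; stop at
`final_reversals` (default 6, even so the median falls between the two
oscillation levels) reversals under step 5, or abort at `max_blocks`
(200). A reversal is logged at the level where the direction changed
and tagged with the step used by the move that reached that level;
phase quotas count only reversals tagged with the phase's own step.
The first direction is "up" by definition, there is no upper level
bound, and the level is floored at 0. Trial truth is an independent
Bernoulli(0.5) draw per trial; the yes/no reading of the task (guess
rate 0.5) is used throughout, with the presentation ratio configurable.
Blocks always run to completion — the published wording ("demonstrated
four consecutive times") suggests no early abort.

The procedure's convergence point is the level where
p(correct)⁴ = 0.5, i.e. the 84.1 %-correct point, and the mean of many
staircase estimates is verified to land within ±3 noise dots of the
analytic value for a known logistic observer.

## Parametric observers and cohorts

`P(correct | n) = γ + (1 − γ − λ)·σ((T − n)/β)` with guess floor
γ = 0.5 (single-presentation yes/no) and lapse rate λ = 0.02 (standard
practice). Cohorts draw per-condition T from normals matched to the
published group means/SDs, truncated below at 1 noise dot, with a
shared observer factor imposing cross-condition correlation ρ = 0.7 —
needed for paired comparisons to behave realistically. The slope
default β = 4 noise dots keeps staircase measurement noise (≈3–4 dots
per estimate) small against the between-observer SDs; since the
staircase measures the 84.1 % point, measured thresholds sit ≈ 0.90·β
≈ 3.6 dots below T. Eccentricity affects parametric observers only
through their condition-specific T — the empirical finding itself —
not through an explicit acuity model.

## Mechanistic detectors

The detectors exist to close the loop from dot coordinates to
thresholds with fully specified, deterministic machinery; they are not
models of cortical motion processing and are not fitted to human
thresholds.

* **Column score.** Stimulus-sized windows slide over the noise field
  on a quarter-window grid (the exact stimulus centre is always a
  candidate). Within a window, for k ∈ {3, 4}, column abscissae are
  fitted by deterministic 1-D k-means (quantile initialization, 25
  iterations) and the 12 dots with the smallest horizontal residual
  are selected; the score is 1 minus the best residual normalized by
  the expectation for 12 uniform dots (12·window/(4k)), clamped to
  [0, 1]. Clean grouped clips score ≈ 1, clean scrambled clips ≈ 0.3.
  The *separation* between classes decays monotonically with noise;
  the raw grouped score itself is non-monotone (moderate noise
  perturbs the fitted abscissae, dense noise supplies column-like dots
  everywhere and saturates both classes — the chance floor).
* **Coherence score.** Per-dot directions from first-to-last
  displacements; the score is the largest cluster of directions within
  ±15° among the dots of the best window, /12, capped at 1. Grouped
  clips score 1; 12 independent uniform directions give expected
  maximum clusters of ~3–4.
* **Walker score.** Minimum over walker templates (5 azimuths ×
  gait-phase shifts every 2 frames × a 3×3 spatial-offset grid of
  ±size/8) of the mean over every 3rd frame of the summed
  nearest-neighbour distance (k-d tree) from the 13 template joints to
  the clip dots, normalized by template height. Lower is more
  walker-like; self-matches score < 0.02, scrambled clips ≈ 1.5.

Criteria are calibrated on noise-free clips (200 per class for the
full pipeline): the midpoint of the score gap when the classes
separate cleanly, otherwise the cut equalizing hit and
correct-rejection rates. Gait phase is sampled on the frame grid so
the template bank can represent every generated phase exactly.

Because the detectors read coordinates perfectly, eccentricity alone
would not degrade them; mechanistic peripheral runs therefore apply a
clearly-labelled demonstration device, isotropic positional jitter
with SD = 0.05·eccentricity deg per dot per frame
(`PeripheralJitter`). It is configurable and off at fixation.

## Statistics

One-way between-groups ANOVA (matching the published df of F(2, 24)
for 27 values from 9 observers × 3 conditions) from raw data or from
group summaries (SSB = n·Σ(mᵢ − m̄)², MSW = mean of variances), the
paired two-sample t-test on differences, and Bonferroni α/m (0.05/3 =
0.017). p-values come from the regularized incomplete-beta based t and
F distribution functions; degenerate inputs are defined explicitly
(zero between- and within-variance → F = 0; zero-variance differences
→ t = 0 or ±∞ with a flag). The raw and summary ANOVA routes agree to
machine precision on matching data, and both are cross-checked against
independent library implementations in the tests.

Published F statistics cannot be recovered exactly from the rounded
printed means/SDs (e.g. the summary route gives F ≈ 41.6 where 42.88
was printed from unrounded data), so exact numeric replication of the
published statistics is not a goal; the significance pattern is.

## Replication harness and what it shows

`replication_rate` simulates complete experiments (cohort → staircases
over the best-size design → aggregation → paired tests) and scores
each against the qualitative pattern: walker > static and
walker > dynamic centrally, static vs dynamic not significant, central
> peripheral within every task, all at α = 0.017. With the default
calibration the directional components replicate almost always
(walker > static ≈ 1.00, central > periphery ≈ 1.00, walker > dynamic
≈ 0.94 of simulated experiments), but the full conjunction holds in
only ≈ half of them: a static–dynamic difference of 11 dots with a
paired-difference SD near 12 sits close to the critical t(8) ≈ 3.0,
so its *non*-significance — itself a marginal outcome (p = 0.06 scale)
— recurs in only ≈ 0.5–0.8 of honest replications under any
calibration consistent with the published summary statistics. This is
a property of the study's effect sizes at n = 9, not of the
simulation: marginal null results do not replicate reliably.

## Aggregation choices

The three repeats of a cell are combined by mean (median available)
before the "best size" maximum over the sizes shown at an
eccentricity; failed staircases are excluded pairwise, never imputed.
Both a per-observer best size (used by default) and a fixed
group-level best size per condition (`best_size_design`) are
available, since the original wording supports either reading.

## Problem sizes used

Defaults keep full runs light: 30-frame clips, 9 observers × 9
conditions × 3 repeats ≈ 250 staircases per simulated experiment
(≈ 0.15 s), 100-experiment replication sweeps, 200-clip-per-class
detector calibrations, and 500-run convergence checks. All scale up
via configuration without code changes.

## Known limitations

* The gait model is a generic sinusoidal approximation; it supports
  structural claims (counts, symmetry, speed), not biomechanical ones.
* Coordinate-level clips only: no rasterization, luminance, contrast
  or acuity modelling, and no eye movements — peripheral degradation
  enters parametric observers only through calibrated thresholds and
  mechanistic ones only through the jitter device.
* The yes/no trial model with a 0.5 presentation ratio is an
  interpretation of an ambiguous procedural description (the original
  names a forced-choice procedure but describes yes/no keys).
* Synthetic cohorts reproduce group moments and correlations, not
  individual human strategy, learning or fatigue; passing tests
  validate the pipeline's internal contracts, not perception itself.
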