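# figground

Simulation toolkit for figure–ground segmentation psychophysics in the
central and peripheral visual field: point-light biological-motion
walkers and Gestalt grouping stimuli embedded in matched visual noise,
block-up-and-down (BUDTIF) threshold staircases, synthetic observers,
and the group-level statistical analysis.

## The problem it models

How many noise dots can a dot stimulus survive before it can no longer
be told apart from its scrambled control? That noise-dot *threshold* is
a classic measure of perceptual organization. The package simulates a
complete study built on three yes/no grouping tasks:

* **static grouping** — 12 equal dots in three or four columns
  (grouping by proximity) vs 12 dots placed at random over the same
  area;
* **dynamic grouping** — the 12-dot column array translating rigidly in
  a common direction (proximity + common fate) vs the same dots moving
  in independent random directions at the same speed;
* **biological motion** — a 13-dot point-light walker (head, shoulders,
  elbows, hands, hips, knees, feet; one full gait cycle; mean dot speed
  9.5 deg/s; one of five walking azimuths) vs its scrambled version,
  whose dots keep their individual trajectories (vertically inverted)
  but start at random positions.

Stimuli appear at 0, 15 or 30 deg of eccentricity, magnified
proportionally in the periphery, and are embedded in visual noise whose
dots share the size and motion statistics of the scrambled stimulus.

### Threshold measurement (BUDTIF)

Each noise level is shown for a block of four trials; the level rises
only if all four responses are correct, otherwise it falls. Starting at
0 noise dots, the step is 20, then 10 after two reversals, then 5 after
two more; the threshold is the median of the step-5 reversal levels.
Because a block moves up with probability `p⁴`, the staircase converges
on the level where

```
p(correct) = 0.5^(1/4) ≈ 0.841
```

For a logistic observer `P(correct | n) = γ + (1 − γ − λ)·σ((T − n)/β)`
this is the analytically known point `T − β·ln[(p − γ)/(1 − λ − p)]`,
and the staircase's mean estimate is verified against it.

### Observers

Two kinds of synthetic observers stand in for the nine participants:

* **parametric** — logistic psychometric responders whose per-condition
  threshold locations `T` are drawn from normal distributions matched
  to the published group means ± SDs (central field walker 94 ± 37,
  dynamic 50 ± 17, static 39 ± 10 noise dots, with peripheral
  declines), correlated within observer through a shared factor;
* **mechanistic** — deterministic detectors that judge the raw dot
  coordinates: a sliding-window column-fit score (proximity), a
  direction-coherence score (common fate), and walker template matching
  over azimuths, gait phases and spatial offsets (body form). Each
  thresholds its score at a criterion calibrated on noise-free clips.

## Worked example

```python
import figground as fg

cohort = fg.sample_cohort(fg.CohortSpec(), seed=11)      # 9 observers
table  = fg.run_design(cohort, fg.best_size_design(), seed=12)
agg    = fg.best_size_aggregate(table)
print(fg.report(agg).to_text())
```

prints (abridged):

```
Summary (mean +/- SE per condition)
   dynamic @    0 deg:   49.4 +/-  5.0 noise dots (n=9)
    static @    0 deg:   37.4 +/-  1.9 noise dots (n=9)
    walker @    0 deg:   98.5 +/-  9.4 noise dots (n=9)
...
One-way ANOVA per family
  tasks@central: F(2, 24) = 26.7996, p = 7.66e-07
...
Pairwise paired t-tests (Bonferroni alpha = 0.017)
  tasks@central: dynamic@0 vs static@0: t(8) = 2.823, p = 0.02239
  tasks@central: static@0 vs walker@0: t(8) = -7.473, p = 7.11e-05 *
```

The walker tolerates far more noise than either grouping task, the
static/dynamic difference misses the corrected alpha, and every task
collapses in the periphery — the qualitative signature the simulation
is calibrated to. `fg.pattern_checks(agg)` evaluates that signature for
one run and `fg.replication_rate(100, seed=...)` measures how often it
recurs across independently simulated experiments.

The `examples/` directory holds short narrative scripts, one per
capability: `generate_stimuli.py`, `run_staircase.py`,
`simulate_experiment.py`, `mechanistic_observer.py`.

## Layout

```
src/figground/
  clip.py        dot/frame/clip containers (deg of visual angle)
  walker.py      parametric 13-joint gait model, scrambling
  grouping.py    static and dynamic 12-dot grouping stimuli
  noise.py       matched visual-noise embedding
  layout.py      size table, eccentric placement, magnification
  io.py          JSON clip files, CSV export
  observers.py   logistic observers, cohort generator
  detectors.py   mechanistic column/coherence/template detectors
  staircase.py   block-up-and-down procedure and threshold estimate
  pipeline.py    per-trial clip synthesis
  experiment.py  design grid, threshold tables, aggregation
  stats.py       ANOVA, paired t, Bonferroni, report
  replication.py significance-pattern replication harness
```

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
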