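# defekit

Digital biomarkers of defecation from smart-toilet sensor streams.

A camera looking into the toilet bowl (with a toilet-state classifier and two
stool-detection filters split at the waterline) and a seat-pressure sensor
together observe a defecation event without capturing any part of the body.
`defekit` turns those two streams into a quantitative description of the
event, models the resulting biomarkers statistically, and asks how well a
person can be re-identified from their defecation habits alone. It is aimed
at researchers in gastrointestinal digital health who want a tested,
reproducible reference implementation of this analysis — including a
synthetic-data generator, so the whole pipeline runs and is validated
without any human recordings.

## What it computes

**Event timeline.** Five anchor times are extracted per event: sit-down
`t0` (first seated pressure sample), first stool drop `t1` (first
above-waterline detection confirmed by the stool state), last drop `tf`,
cleansing start `tt` (first stool → toilet-paper transition) and event end
`te` (return to the clean state), with

```
ADD = tf − t1   (active defecation duration)
TDD = te − t0   (total defecation duration)
ETD = tt − tf   (eu-tenesmus: last drop to cleansing, in healthy subjects)
```

Cleansing posture is seated or standing depending on whether toilet paper
appears before or after the final pressure release.

**Optical calibration.** A detected pixel width becomes a physical stool
thickness through a position-dependent transformation coefficient
`y(x) = 0.092840 (0.000037 x^1.497 + 1)` mm/px, where `x` is the pixel
count from the image bottom to the drop location; equivalently through the
pinhole chain `D = 2 d tan(FOV/2) · P_stool / P_img` at a measured
camera distance `d` (193 / 237 / 290 mm for the rear / center / front drop
positions). The time between the first above-waterline and first
below-waterline detection is the stool-dropping duration (SDD).

**Biomarker statistics.** Eleven biomarkers per event (DT, SDD, FSD, ADD,
TDD, ETD, ST, BSFS, SC, CT, U). Dropping durations are fit by a closed-form
log-normal MLE (`μ̂ = mean ln x`, `σ̂ = sd ln x`). Group comparisons use an
IQR outlier fence (multiplier 1.5), a Shapiro–Wilk normality gate, then
Welch's t-test or the Mann–Whitney U test, two-sided at α = 0.05 —
including the five Bristol stool form scale contrasts ({1,2} vs {3}, {3} vs
{4}, {4} vs {5}, {5} vs {6,7}, and pooled {1,2,3} vs {5,6,7}) and the
gender contrast of eu-tenesmus; stool thickness is regressed on dropping
duration by OLS.

**Biometric feature search.** Every subset of ≥ 3 biomarkers (1,981 subsets
of the 11) is Min-Max normalized, embedded in 2-D with t-SNE, and scored by
the silhouette coefficient `s(i) = (b(i) − a(i)) / max(a(i), b(i))` against
predefined participant labels; subsets are ranked per category grouping
(time+shape, time+behavior, shape+behavior, all).

## Worked example

```python
import defekit as dk

cohort = dk.generate_cohort(11, 5, seed=1)            # 5 female, 6 male
dataset = dk.simulate_dataset(cohort, 5, seed=1)      # raw sensor streams
table = dk.assemble_features(dataset)                 # extract biomarkers
print(f"{len(table)} events from {len(cohort)} participants")

pooled = dk.bsfs_contrasts(table, "ST")[-1].result
print(f"thickness, BSFS 1-3 vs 5-7: {pooled.means[0]:.1f} vs "
      f"{pooled.means[1]:.1f} mm, {pooled.test_used}, p = {pooled.p_value:.2g}")

reg = dk.linear_fit(table["SDD"], table["ST"])
print(f"thickness ~ dropping duration: slope {reg.slope:.2f} mm/s, "
      f"R^2 = {reg.r_squared:.2f}")

for r in dk.rank_subsets(table, "time+behavior", seed=1)[:3]:
    print(f"  {'+'.join(r.subset):24s} S = {r.score:.3f}")
```

prints

```
55 events from 11 participants
thickness, BSFS 1-3 vs 5-7: 38.4 vs 15.1 mm, mann_whitney_u, p = 1.1e-08
thickness ~ dropping duration: slope 6.28 mm/s, R^2 = 0.97
  DT+TDD+ETD               S = 0.144
  DT+SDD+ETD               S = 0.113
  DT+SDD+TDD+ETD           S = 0.096
```

Constipated-range stool (Bristol 1–3) is markedly thicker than
diarrhea-range stool (5–7); thickness rises linearly with dropping
duration; and the best person-identifying biomarker subsets combine the
habitual timing parameters (hour of day, durations) — stool-shape
parameters vary day to day and identify people poorly.

A command-line interface wraps the same pipeline:

```bash
defekit run-all --seed 1 --output out/
```

writes `events.csv`, `biomarkers.csv`, `stats_report.json`,
`silhouette_rankings.csv`, `longitudinal.json` and a manifest; identical
configurations produce byte-identical outputs.

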