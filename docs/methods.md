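# Methods

## The measurement model

A monitored defecation event is observed through two streams. The optical
stream consists of frames named `hhmmss.ssss` (0.1 ms time resolution),
each carrying a toilet-state label — `clean`, `urine`, `stool`,
`toilet_paper` — and zero or more stool detections (pixel row from the
image top, pixel width). Detections above the waterline row (default 1300
of a 2592-row image) come from the *stool-dropping* filter, those at or
below it from the *stool-dropped* filter; a detection exactly on the
waterline counts as dropped (at the water surface). The pressure stream is
a boolean seated flag over time.

### Timeline extraction

* `t0` — first seated pressure sample.
* `t1` — first dropping-filter detection that is double-confirmed by the
  state stream: a `stool`-state frame must occur at or before the
  detection frame plus a two-frame window (the confirmation window is a
  package choice; it bounds spurious single-frame detections without
  delaying `t1` by more than two frames).
* Drop episodes — consecutive dropping detections less than 1.0 s apart
  belong to one stool piece; a new episode starts after a longer gap or
  after a dropped-filter confirmation. The episode count is the stool
  count (SC).
* `tf` — the first dropping-detection time of the last episode (for a
  single-drop event `tf = t1` and ADD = 0).
* `tt` — the first `stool → toilet_paper` state transition at or after
  `tf` (toilet-paper use before the last drop does not count as cleansing).
* `te` — the last transition into `clean` after `tt`; a stream that never
  returns to clean is rejected as truncated.

Cleansing posture: standing when the final seated→unseated pressure
transition precedes the first toilet-paper frame, else seated. Urination
order: before (U = 1) when a urine-state frame precedes `t1`; otherwise
U = 0 with a separate `urination_observed` flag, since a stream with no
urine state cannot distinguish "after" from "none".

The derived durations ADD = `tf − t1`, TDD = `te − t0`, ETD = `tt − tf`
are exact arithmetic; on simulated streams every anchor is recovered to
within one frame interval (verified at 0.1 s and 0.5 s).

### Optical calibration

Two equivalent pixel→mm routes are implemented and cross-checked. The
pinhole chain uses the camera's horizontal field of view (66°, the public
specification of the camera module, as the recordings' metadata does not
state it) and the measured camera-to-drop distance `d` ∈ {193, 237, 290}
mm (taken to be millimetres, consistent with thickness units):
`mm/px = 2 d tan(FOV/2) / P_img` with `P_img = 2304`. The fitted
transformation coefficient is `y(x) = a (b x^c + 1)` with
`(a, b, c) = (0.092840, 0.000037, 1.497)` and `x` the pixel count from the
image *bottom* (`x = image_height − row`; the two row conventions are
converted explicitly). The grouped reading of the constants is adopted
because it is the only one that yields mm-per-pixel magnitudes
(0.09–0.25 over the bowl) dimensionally consistent with the pinhole chain;
the ungrouped literal reading exceeds 1 mm/px everywhere and is retained
only as a comparison variant. At the three calibrated distances the two
routes agree to < 0.04%, and a known width survives mm → integer px → mm
within half-pixel quantization plus the 2% model residual.
`fit_coefficient` recovers (a, b, c) from noiseless synthetic calibration
points to ~1e-7 relative. Which x corresponds to which distance is fixed
by inverting the coefficient against the pinhole factor, which guarantees
monotone consistency without asserting an unverifiable front/rear mapping.

## Statistical workflow

Per analysis variable, independently: single-pass IQR fence
(`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, quartiles by linear interpolation — the
mainstream numeric default; the convention is configurable), then a
Shapiro–Wilk gate at the comparison α in both groups choosing Welch's
t-test (both normal) or the Mann–Whitney U test, two-sided, α = 0.05.
Under a Gaussian null the full gate-then-test procedure rejects at
0.048 over 2,000 replicates (n = 20 per group). No multiplicity
correction is applied by default, mirroring raw-p-value reporting; a
Bonferroni/Benjamini-Hochberg option exists. Bristol contrasts with fewer
than three observations in either group are flagged not-computable rather
than raising, so the remaining contrasts are still reported.

Log-normal fitting is the closed-form MLE on logs (denominator n). The
method-of-moments inversion `σ² = ln(1 + (sd/mean)²)`,
`μ = ln mean − σ²/2` is provided for comparing a fitted law against
published arithmetic summaries: inverting mean 3.214 s / SD 3.800 s gives
(μ, σ) = (0.730, 0.935) versus the fitted (0.694, 0.932) — a fit-method
difference (MLE on raw data vs moment inversion of its summaries), not a
discrepancy, and the package documents rather than equates them.

## Biometric feature search

The 11 biomarkers fall into three categories: time-dependent (DT, SDD,
FSD, ADD, TDD, ETD), shape-dependent (ST, BSFS, SC), behavior-dependent
(CT, U). All subsets of size ≥ 3 are enumerated (1,981 = 2¹¹ − 1 − 11 −
55); a grouping's eligible subsets are those drawn from the union of its
categories, which reproduces the pairwise-grouping report while covering
the full 1,981 under "all". DT enters as the integer hour 0–23 (a
cyclic encoding is deliberately not applied by default, matching the
declared integer type; gender is excluded from the feature set). Min-Max
normalization maps each non-constant column to [0, 1] (constant columns
to 0) and passes binary columns through unchanged. The 2-D embedding is
t-SNE with PCA initialisation, a fixed seed recorded in the output, 500
iterations, and perplexity `min(30, (n−1)/3)` — unstated hyperparameters
fixed once as package defaults. The silhouette is computed on the 2-D
embedding against predefined participant labels with Euclidean distance;
singleton clusters score 0 (the standard convention). A raw-feature
scoring mode (`use_embedding=False`) is provided for comparison. The
implementation is verified against an independent brute-force pairwise
computation to 1e-12 and against scikit-learn where the latter is defined.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis expects of
real recordings; its defaults are the study conditions.

* **Cohort**: 11 participants (5 female, 6 male), 5 events each (55
  events) over up to 22 distinct days; the per-participant event count is
  a parameter.
* **Dropping duration**: log-normal, marginal log-mean 0.694 / log-SD
  0.932 (median ≈ 2 s, heavy right tail), split into a per-participant
  offset (log-SD 0.40 — chosen so per-participant *average* durations
  span roughly 1–5 s) plus within-participant noise carrying the rest of
  the variance.
* **Thickness**: `T = 5.1 + 6.68 · SDD + N(0, 5) mm`, floored at 2 mm.
  The intercept places mean thickness near 26–27 mm at the mean dropping
  duration; the 5 mm noise puts the thickness–duration R² near 0.96.
* **Bristol score**: banded on the event's mean thickness at the midpoints
  of the calibrated per-group means (35.05 / 27.75 / 21.7 / 17.65 mm), so
  thicker stool gets a lower score by construction; within {1,2} and
  {6,7} the participant's Bristol-weight habit picks the specific score.
  A `force_bsfs_group` mode instead samples thickness from the calibrated
  per-group Normal (38.5±6.4, 31.6±8.7, 23.9±10.0, 19.5±7.7, 15.8±3.7 mm)
  and back-derives the dropping duration through the same slope — used
  when a fixed stool form is required, e.g. to verify the calibration
  table itself. (The band-conditional means of the default path do not
  equal the calibration means — a long-tailed marginal cannot have both —
  which is why the forced mode exists.)
* **Eu-tenesmus**: log-normal truncated to [3.6, 301.7] s with
  gender-specific location (moment-matched to female mean 114.6 / SD
  100.6 s, male 48.2 / 32.4 s; upper truncation biases the female mean
  a few percent low). Person effect and day noise split 3:1 in variance.
* **Other habits**: typical hour (uniform 6–22, day jitter SD 1.5 h),
  first-stool delay (population mean 25 s, between-person SD 10 s),
  cleanup tail (mean 29 s), seated-cleansing and urination-first
  probabilities each Beta(2,2) per person (≈ 50/50 marginally). The 3:1
  between:within variance ratio for habitual traits gives the biometric
  search its signal; the shape chain deliberately inherits only the
  moderate 0.40 person component, since day-to-day stool form is far less
  habitual than timing and behaviour.
* **Stool count**: 1 + Poisson(2); multi-drop events spread drops over a
  Gamma-distributed active phase (mean ≈ 21 s) with at least
  `SDD + 1.2 s` between drop starts, so mean ADD lands near 18–21 s and
  TDD near 140–150 s.
* **Streams**: frames every 0.1 s (configurable; the recovery guarantee
  scales with the interval). Each drop emits dropping-filter detections
  from its start until its splash and dropped-filter detections for 0.4 s
  after, with pixel widths equal to the mm thickness divided by the local
  transformation coefficient, rounded to integer pixels; drop locations
  are drawn uniformly from rear/center/front and placed at the image rows
  where the fitted coefficient matches the pinhole factor. Pressure goes
  seated at `t0` and releases before the first toilet-paper frame
  (standing) or after it (seated), consistently with the drawn cleansing
  type.

Ground truth satisfies the three duration identities with zero tolerance.
All randomness flows from explicit seeds; identical inputs give
byte-identical outputs.

### What the generator does not emulate

Real images and their segmentation errors; BSFS classification (labels
are ground truth by default, with a classifier plug-in hook); eventless
urination; a second defecation round after toilet-paper use; flushes;
diet- or stress-driven day-to-day physiology; drift in habits over time.
Passing tests therefore validate the extraction, calibration, statistics
and search machinery — not the performance of any image classifier on
real scenes, and not clinical claims.

## Numerical and design choices

* Quartiles: linear interpolation (configurable).
* Outlier fencing is applied per analysis variable; a single global
  event-exclusion pass is not reproducible from published summaries and
  is not attempted.
* t-SNE determinism comes from PCA init + fixed `random_state`; scores
  are invariant to participant relabelling but not to the embedding seed,
  which is therefore recorded in every ranked output.
* With 11 participants and ~5 events each, single-cohort significance
  checks are noisy: the gender eu-tenesmus test has roughly 80–85% power
  at these sizes, and between-participant clustering inflates the
  effective type-I rate of the Bristol-null checks above nominal.
  Validation of the generator's directional structure therefore
  aggregates over replicate cohorts instead of betting on one draw.
* Degenerate inputs: empty samples pass through the IQR fence; constant
  regressors, sub-minimum samples, single-label silhouettes, streams
  without stool/toilet-paper/clean phases all raise typed errors rather
  than returning garbage.

## Known limitations

The coefficient constants, calibration distances and duration
distributions describe one specific bowl/camera geometry and a small
healthy adult cohort; transferring to other hardware requires refitting
`y(x)` (`fit_coefficient`) and re-measuring the drop distances. ETD means
are a few percent below nominal because of the range truncation. The
timeline engine assumes one defecation round per event; multi-round
events would need a segmentation extension.
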