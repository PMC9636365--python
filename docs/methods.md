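# Methods

## The diagnostic model

The model assumes that during phases of tolerable training load an athlete's
five monitored parameters fluctuate around a stable individual level, and
that maladaptation shifts each of them in a known direction: perceived
fatigue (POMS fatigue subscale) and session RPE rise, while peak session
heart rate and end-of-session blood glucose and lactate fall. Between-subject
differences in absolute levels are large, so all scoring is relative to an
**individual baseline**: the mean of a subject's values over the
normal-reference phases (BL, LT, MT1, RE by default). The **cut-off** per
parameter is a group quantity — half the difference between the cohort mean
in the designated maladaptive phase and the cohort mean under normal load —
so a single cohort calibration yields thresholds applicable to each
individual's deviations. A parameter scores 1 in a phase when the deviation
exceeds the cut-off *strictly* in the adverse direction; 3 or more of 5
scores classifies the subject-phase as maladapted.

Assumptions worth keeping in mind:

- Baseline phases must genuinely be unaffected by maladaptation; including a
  maladapted phase in the baseline dilutes the very signal being tested.
- The cut-off calibration needs a cohort that actually contains a maladapted
  phase for at least two subjects.
- Parameters are combined by counting, not weighting: each contributes
  equally regardless of its measurement precision.

### Numerical and design choices

- **Tie rule.** A deviation exactly equal to the cut-off scores 0. "Deviates
  more than the cut-off" is read as a strict inequality; ties at floating
  point are only meaningful for exactly representable values, and the test
  suite exercises that case with binary-exact numbers.
- **Cut-off precision.** Cut-offs are computed and applied at full precision.
  The published display table rounds inconsistently (4.65 prints as 4.7 but
  0.715 as 0.71, 2.55 as 2.5, 0.625 as 0.62), so printed values are treated
  as display artifacts; a `fixed` mode applies any externally supplied values
  (including the printed ones) verbatim, and the report records which mode
  and which exact values were used.
- **Group-mean pooling.** The default pools all subject × normal-phase
  observations with equal weight; a `subjects` mode averages within subject
  first. The two differ only for unbalanced panels.
- **Missing data.** A missing observation scores 0 and is flagged
  (conservative: it can only reduce, never create, a maladaptation call). A
  missing baseline phase reduces the baseline to the mean of the remaining
  normal phases with a warning; a subject with no usable normal-phase value
  for a parameter is a hard error.
- **Individual cut-offs.** A per-subject mode (half the subject's own
  MAL-vs-baseline shift) is available for experimentation. It is not the
  default: single-subject calibrations are unstable and can produce
  implausibly small or large thresholds.
- **MT2.** The second moderate phase is scored and classified like any test
  phase but contributes neither to baselines nor to cut-off derivation.
- **Correlation.** The score–respiration association uses Pearson r with the
  standard two-sided t-transform on n−2 degrees of freedom, restricted to
  phases with biopsies (no biopsy exists for MT2). No multiple-testing
  correction is applied: it is a single pre-specified association. Zero
  variance in either vector is an explicit error, not r = 0.
- **Pooled statistics.** Stratified means are pooled by sample-size weighting
  and rounded half-away-from-zero to the printed precision of the inputs.
  Age is the one whole-cohort characteristic that does not reproduce from
  rounded sex-stratified means (305/11 = 27.7 rounds to 28, not the printed
  27); it is excluded from the pooled-statistics checks.

## Session metrics

All signals are linearly resampled to a 1 Hz grid before windowing (device
export dialects vary; the resampling is the only signal cleaning performed).
Windows slide one sample at a time with inclusive start; ties go to the
earliest window. Session HR_max is the highest 30-s mean anywhere in the
session; interval VO₂ is the highest consecutive 120-s mean within the
interval; power and heart rate use full-interval means. Heart-rate recovery
at time t is the bout's peak 30-s heart-rate mean minus the heart rate t
seconds after bout end, averaged over intervals into a session mean; a
truncated recovery record reports the affected time point as missing.

Substrate oxidation uses stoichiometric coefficients
fat = 1.695·VO₂ − 1.701·VCO₂ and CHO = 4.170·VCO₂ − 2.965·VO₂ (g/min, gases
in L/min). Negative rates (RER outside 0.7–1.0) are clipped to zero with the
raw value retained and a note emitted. Energy expenditure defaults to
3.820 kcal/L O₂ + 1.150 kcal/L CO₂; both coefficient sets are configurable
and recorded in the output, since oxidation-calorimetry constants differ
slightly between sources. Gross efficiency is mechanical power over
metabolic power (the caloric estimate converted to watts) × 100. All ratios
(W/HR, HR/RPE, lactate/RPE, …) are guarded: a zero or invalid denominator
yields a flagged missing value, never an infinity.

One caveat the tests encode: the peak windowed mean is ≥ the overall series
mean only when the window length divides the series length (the overall mean
is then a convex combination of window means). With overhanging windows the
bound can fail (series [1, 0, 1], window 2), so it is asserted only in the
tiling case.

## Synthetic cohort

The generator emulates the study conditions: 11 subjects, six phases, five
parameters, and a maladaptive phase defined by a ~40% loss of intrinsic
mitochondrial respiration.

- **Reference score matrix.** The published marginals (per-parameter positive
  counts per phase; cumulative ≥ k-of-5 counts per phase) do not identify
  which subject got which score. The canonical fixture is a deterministic
  greedy construction per phase: subjects in descending score-total order,
  each assigned to the parameters with the largest remaining capacity,
  index-order tie-breaks. Feasibility is pre-checked with the Gale–Ryser
  condition and errors name the violated phase and bound. A seeded
  randomized assignment consistent with the same marginals is available for
  sensitivity checks.
- **Measurement panels.** Each subject-parameter gets an anchor drawn from
  the published normal-phase group mean with a between-subject SD
  (plausible defaults — the study prints only figure error bars — and
  user-overridable). Target deviations are placed at 1.2–2.0× the cut-off
  for positive cells and 0–0.8× for zero cells, with the normal-phase
  targets balanced to sum to zero so the recomputed individual baseline
  equals the anchor and every realised deviation equals its target; the
  round trip (re-scoring the generated panel returns the input matrix) is
  therefore exact by construction, and is verified post hoc with a bounded
  redraw budget after physiologic clipping (RPE into 6–20, concentrations
  ≥ 0). A matrix demanding a positive score in *all* normal-reference phases
  of one parameter is rejected as infeasible: a value cannot exceed its own
  all-phase mean everywhere.
- **Respiration.** Subject levels ~ Normal(100, 15) in arbitrary units with
  within-subject SD 8; the maladaptive phase mean is shifted by −40% of the
  subject level. Only the relative effect is anchored to the study; the
  absolute scale is free. No record is generated for MT2 (no biopsy).
- **Sessions.** 10-min 100 W warm-up, 2-min rest, five 4-min intervals at
  ~250 W with 3-min passive rests; heart rate relaxes exponentially toward
  segment targets (τ = 45 s in work, 60 s in rest), VO₂ tracks power through
  a first-order response and VCO₂ is RER·VO₂ (default RER 0.95).
- **Effect-size cohorts.** For classifier-recovery simulations a mean-shift
  generator draws every phase around the subject's level with measurement
  noise (default SD = half the cut-off) and shifts only the maladaptive
  phase by the published effect sizes, leaving the pipeline to re-derive
  baselines and cut-offs from the simulated data itself.

### What passing tests do and do not show

The generators reproduce the study's *score structure* and marginal effect
sizes, not real physiology: parameters are drawn independently (real fatigue,
RPE and lactate covary), within-subject noise is Gaussian and homoscedastic,
and no session-to-session autocorrelation or placebo/learning effects exist.
Tests passing on synthetic cohorts show the arithmetic, the classifier logic
and the calibration machinery are correct; they do not validate the
diagnostic's sensitivity or specificity in new athlete populations, which
requires prospective data.

## Problem sizes

The test suite runs the brute-force scoring comparison on 500 random cohorts
of ≤ 12 subjects, the measurement round trip over 100 seeds, the
score–respiration sign check over 500 simulated cohorts, the windowed-peak
exhaustive comparison over 1000 random series, and the respiration
calibration at 1000 subjects — sizes at which the checked properties are
already stable.

## Known limitations

- Cut-off derivation requires a maladapted phase in the calibration cohort;
  the package does not (and cannot) invent thresholds for cohorts that never
  maladapted. The `fixed` mode exists precisely to reuse published values.
- POMS subscale scaling follows the scoring software used in the source data
  (values exceed the raw 0–28 subscale range); units are treated as opaque
  score units throughout.
- The published per-phase respiration trajectory and the published
  score–respiration correlation coefficient depend on subject-level data
  that were not deposited, so they are checked only qualitatively (sign and
  approximate effect size) on synthetic cohorts.
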