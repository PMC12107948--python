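# Methods

## Setting and quantities

Patients in shock are managed with vasopressors titrated to a MAP target.
The package models a two-arm design: a *standard* arm targeting the
conventional default of 65 mmHg, and an *individualized* arm targeting the
patient's own pre-illness MAP (clamped to 55–95 mmHg, ± 2 mmHg). The study
clock starts at T0, the first continuous vasopressor/inotrope infusion, and
observation continues until the patient has been vasopressor-free for 24 h
or to 120 h, whichever is earlier. MAP and norepinephrine-equivalent dose
are charted 4-hourly; creatinine as a daily peak.

## Pre-illness MAP

Cuff readings convert to MAP by `DBP + (SBP − DBP)/3`. Selection is greedy
from the most recent reading backwards within a 3-year look-back
(implemented as 3 × 365.25 days), keeping a reading only if it is ≥12 h
from every reading already kept, up to 5 (minimum 2). Clinic-type sources
(ambulatory, outpatient, pre-admission, echo clinic) form the primary pool;
observation-chart readings from the last 48 h of a prior hospitalization are
a *fallback pool* consulted only when the clinic pool cannot supply two
readings — the two pools are never mixed, which keeps the provenance of the
estimate homogeneous. The pre-illness MAP is the unweighted mean of the
selected readings' MAPs.

The ±2 mmHg band is applied **after** clamping the target center to
[55, 95] mmHg (an estimated 100 mmHg yields 93–97): the clamp defines the
target, and the band describes permitted titration slack around whatever
target is actually set. The standard arm is represented as a degenerate
band (low = high = center): it is a floor-style default, not a window.

## Exposure metrics

The deficit signal `d(t) = 100 (m₀ − MAP(t))/m₀` (m₀ = pre-illness MAP) is
signed; negative excursions mean overshoot. The headline summary is the
time-weighted average of the **positive incremental AUC**: `d(t)` is taken
piecewise-linear between observations, zero-crossings are located exactly
within each segment, the positive part is integrated analytically, and the
area is divided by the span from first to last observation. This is *not*
the same as clamping sampled values before trapezoid integration; the test
suite pins the convention against a fine-grid quadrature oracle at 10⁻⁶
relative tolerance.

Threshold-time fractions (% time with deficit >20%, % time with MAP
< 65 mmHg) classify each inter-observation interval by its **left endpoint**
(last observation carried forward — a chart value describes the state until
the next measurement). The denominator is the total time in intervals with
both endpoints observed and length within the nominal 4-h charting interval;
an interval adjacent to a missing observation is excluded from numerator and
denominator alike. Missing MAPs are never interpolated for these metrics.
Achieved MAP is the plain trapezoidal time-weighted mean. Daily summaries
use 24-h windows anchored at T0 (day 1 = [0, 24) h), not calendar days.

Where raw vasopressor doses must be combined, the norepinephrine-equivalence
table defaults to norepinephrine 1.0, epinephrine 1.0, phenylephrine 0.1
(µg/kg/min), vasopressin 2.5 per U/min; dobutamine is an inotrope and is
excluded. The table is a configurable argument.

## Renal endpoints

KDIGO staging uses the creatinine/RRT arms only (urine-output staging needs
hourly urine data, which the charted variables do not include): stage 3 on
RRT, creatinine ≥3× baseline, or ≥353.6 µmol/l; stage 2 at ≥2× baseline;
stage 1 at ≥1.5× baseline or an absolute rise ≥26.5 µmol/l. With only daily
peaks, the 48-h qualifier of the absolute-rise criterion is approximated by
also comparing adjacent-day peaks. A missing pre-morbid baseline is
back-estimated from the MDRD equation (coefficient 175, no race term) at an
assumed eGFR of 75 ml/min/1.73 m², converted at 88.4 µmol/l per mg/dl.

MAKE-14 = death ≤ day 14, new RRT ≤ day 14, or creatinine doubling from the
**pre-morbid baseline** assessed at min(day 14, ICU discharge day) using the
last daily peak at or before that day. The randomization creatinine is the
denominator only for the % peak creatinine rise, which is undefined for
patients receiving RRT within 14 days. "New significant AKI" is a peak
stage shift ≥2 relative to the stage implied by the randomization-day
creatinine. A patient with no assessable creatinine and no other component
is recorded as no-doubling with a warning rather than an error.

## Statistics

* **Fisher exact, two-sided**: conditional on both margins, the p-value sums
  hypergeometric point probabilities ≤ the observed table's (point-probability
  convention, the dominant one), with 10⁻⁷ relative slack for floating-point
  ties; degenerate margins give p = 1. Tested against an exact-rational
  exhaustive enumeration oracle.
* **Wilcoxon rank-sum**: exact enumeration when m+n ≤ 20 without ties,
  otherwise normal approximation with continuity and tie correction.
* **Mixed models**: random intercept per patient; fixed effects treatment,
  days from T0 to randomization (linear), days since randomization (linear),
  treatment × time. REML fit with Wald 95% CIs; non-convergence falls back
  to ML with a warning. Degrees-of-freedom corrections
  (Satterthwaite/Kenward–Roger) are not applied — a known divergence risk
  from other software on small samples.
* **Group summaries**: medians with 25th/75th percentiles by linear
  interpolation; counts with percentages.
* **Sample size**: two proportions by the classical formula (pooled variance
  under the null, unpooled under the alternative), the unrounded total
  inflated by 1/(1 − attrition) and then rounded up once; z-quantiles at full
  double precision. Two means by 2(z₁₋α/₂+z₁₋β)²σ²/δ², rounded up per group.
  With δ = 8, σ = 9, α = 0.05, power 0.8 the two-mean formula gives 20 per
  group (40 total); pilot protocols sometimes quote a larger figure (e.g. 50)
  after unstated inflation for nonparametric efficiency or attrition — the
  calculator returns the formula value and leaves any inflation explicit to
  the caller.

## Synthetic-data generator

The generator emulates the data *structure* and headline marginals of a
pilot-scale MAP-target trial; it fits nothing to patient-level data.

* Pre-illness MAP ~ Normal(95, 8) mmHg, realized through 2–5 simulated cuff
  readings (per-reading noise SD 3 mmHg) so the estimation pipeline itself
  produces the value used downstream.
* Randomization: permuted blocks with random even sizes (default {2, 4}),
  stratified by site (default two sites with 22:15 recruitment weights).
* Hemodynamics: stationary AR(1) at 4-h resolution, coefficient 0.6,
  stationary SD 6 mmHg, mean = the arm's achieved-MAP center. The standard
  arm's center defaults to 77 mmHg — not 65 — to emulate the well-documented
  overshoot of real-world titration above the default target; the
  individualized arm centers on its target. Duration is log-normal with
  median 90 h and log-SD 0.8 (between the two arms' typical 72–107 h spans),
  truncated at 120 h. No physiological model is attempted or implied.
* Vasopressor dose = gain × (center − latent unsupported MAP) + noise,
  floored at 0, with gain 0.01 µg/kg/min per mmHg.
* Creatinine: baseline log-normal (median 80 µmol/l, log-SD 0.25);
  randomization value a log-normal lift (median 1.6×). Daily multiplicative
  steps move up (mean +0.18 on the log scale) with probability
  σ(−2.5 + 0.06 × deficit%) and drift down otherwise; stage-3 days trigger
  RRT with probability 0.3; 14-day death occurs with base probability 0.12,
  uniform over days 1–14.
* Seeding: one master `SeedSequence`, spawned per patient, so adding a
  patient never perturbs existing trajectories.

What passing tests on these cohorts show: the pipeline recovers configured
separations and effects under clean AR(1)/log-normal dynamics. What they do
not show: robustness to real-data features the generator omits — informative
censoring of vitals by death or deterioration, clinician target overrides,
device artefacts, correlated missingness, or nonstationary shock evolution.
Death timing is generated independently of the MAP trajectory; the two are
linked only through the deficit→AKI channel.

## Problem sizes and numerical choices

Simulation-based checks use 500-patient cohorts with 100 seeded replicates
for separation ordering, 2000 replicates for Fisher type-I calibration, and
200 replicates (n = 60 patients × 5 days) for mixed-model CI coverage,
with single-dataset recovery at n = 100; these sizes give Monte-Carlo error
comfortably below the asserted margins. Quadrature oracles use grids of
0.001–0.0025 h. Percentages are kept on the 0–100 scale throughout.
Deficit-bin boundaries are <10, 10–20 (inclusive), >20. Ties in the Fisher
point-probability comparison are absorbed by 10⁻⁷ relative slack.

## Known limitations

* Interval classification (left-endpoint) and the positive-part integral are
  stated conventions; charting systems that clamp samples before integrating
  will differ slightly near zero-crossings.
* KDIGO urine-output criteria, cystatin-C, and eGFR trajectories are out of
  scope; staging from daily peaks cannot see sub-daily creatinine dynamics.
* Mixed-model CIs are Wald-type; small-sample coverage can run slightly
  below nominal relative to Kenward–Roger-corrected software.
* The generator's marginals are targets, not fits; it is a test harness for
  the pipeline, not a digital twin of any ICU population.
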