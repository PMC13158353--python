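# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `akival`.

## Reference standard: KDIGO creatinine phenotype

All dates are integer day offsets from hospital admission (day 0). The
source systems the package models record laboratory values at daily
resolution, so "within 48 hours" is calendar-day arithmetic (day difference
≤ 2), and repeat same-day tests are collapsed to their maximum before
adjudication (`daily_max`).

**Baseline creatinine.** Three definitions are implemented:

* `mean_outpatient_7_365` (default): arithmetic mean of outpatient SCr
  values drawn 7–365 days before the index surgery;
* `latest_outpatient_7_365`: most recent value in the same window;
* `latest_inpatient_presurgery`: most recent inpatient value strictly
  before the surgery day.

A patient with no qualifying value raises a `BaselineUnavailableError`,
which eligibility converts into an exclusion rather than a failure. The
baseline eGFR uses the Japanese equation
`194 · SCr^-1.094 · age^-0.287` (× 0.739 for women), and strata are
≥60.0, 30.0–59.9, 15.0–29.9 and <15 mL/min/1.73 m².

**Adjudication rules.** Within the detection window (surgery day through
discharge by default; surgery day + 7 days for sensitivity analysis 1):

* *relative rise*: any post-operative value ≥ 1.5 × baseline; the stage is
  the half-open band of the peak ratio — [1.5, 2.0) → 1, [2.0, 3.0) → 2,
  [3.0, ∞) → 3. Half-open bands match the usual "1.5–1.9 / 2.0–2.9 / ≥3.0"
  phrasing without gaps at reporting precision.
* *absolute rise*: a value exceeding by ≥ 0.3 mg/dL the minimum of all
  values observed in the preceding 2 calendar days (inclusive), with the
  baseline estimate treated as if observed on the surgery day. This is the
  KDIGO-faithful rolling-48-h reading; the stricter variant that compares
  only against the baseline within 2 days of surgery is available as
  `absolute_comparator="baseline"`. The absolute rule alone implies stage 1.
* *SCr ≥ 4.0 mg/dL* promotes to stage 3. By default
  (`scr4_requires_aki=True`) the promotion applies only when a rise rule
  also fires, matching the KDIGO requirement that the criterion marks the
  severity of an established AKI; setting it to `False` counts a lone high
  value as stage 3. Because patients with baseline SCr ≥ 4 or eGFR < 15 are
  excluded upstream, the two readings rarely disagree.
* *RRT*: a hemodialysis (J038) or peritoneal-dialysis (J042) procedure on
  or after the surgery day, inside the window, is stage 3 regardless of
  creatinine.

The trigger is the rule firing on the earliest day; same-day ties go to the
higher-stage rule, then to the relative rule. An empty post-operative
series without RRT yields a negative adjudication flagged `evaluable=False`
so that eligibility, not the phenotyper, decides the patient's fate.

**A note on monotonicity.** Raising a *single* intermediate value can lift
the rolling 48-h minimum and un-fire a later absolute rise (baseline 1.0
at day 0, values 1.0 at day 2 and 1.31 at day 4: positive; raising day 2 to
1.25 makes it negative). This is inherent to any rolling-window criterion,
not an implementation artifact. Monotonicity does hold — and is
property-tested — for (a) uniform scaling of all post-operative values
under the rolling comparator and (b) single-value increases under the
baseline-only comparator.

## Eligibility cascade

A hospitalization is analyzed when *all* of: age ≥ 18; the index surgery
(the first of the stay) occurs within 7 days of admission; at least one
outpatient SCr lies 7–365 days before surgery; at least one inpatient SCr
falls within 2 days after surgery; no renal-transplant marker (ICD-10
Z94.0 in any role, or procedure K780/K780-2); no maintenance dialysis
(J038/J042 under an ESRD comorbidity at admission — matched as ICD-10
N18.5 — or any dialysis on or before the surgery day); and baseline SCr
< 4 mg/dL with baseline eGFR ≥ 15. ICD-10 matching is prefix-based after
dot-stripping, so `N17`, `N17.0` and `N170` are equivalent.

Every criterion is record-intrinsic, so the final cohort is invariant to
ordering; the ordering only attributes counts in the attrition table
(conservation `initial = final + Σ excluded` is asserted). The two
missing-creatinine rows can be merged with `group_missing=True`, the way
selection flowcharts often group them. Dialysis *after* surgery without an
ESRD comorbidity is an outcome (RRT), never an exclusion.

## Diagnostic accuracy

`build_contingency` cross-classifies the KDIGO reference against the coded
index test. The index test is positive when any diagnosis in the
*in-hospital complication* role matches the code set; comorbidity-at-
admission entries never count. Code sets: `n17_only` (N17 block by prefix)
and `expanded` (adds exact N19, unspecified renal failure, and N99.0,
postprocedural renal failure — sensitivity analysis 4). Stage-restricted
references (`min_stage` 2 or 3) keep the full cohort denominator and move
lower-stage AKI to the reference-negative side.

Interval methods:

* proportions — Clopper–Pearson exact bounds from beta quantiles,
  `Beta(x, n−x+1)` and `Beta(x+1, n−x)`; chosen because the exact method
  reproduces the published sensitivity CI for 27/663 (2.7–5.9%) where
  Wilson gives 2.8–5.9%;
* likelihood ratios — Simel log method,
  `SE(ln LR+) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN))` and the analogous
  form for LR−;
* DOR — Woolf log method, `SE(ln DOR) = √(1/TP + 1/FP + 1/FN + 1/TN)`,
  documented as approximate: on the reconstructed overall table it yields
  16.1–78.6 while the source prints 16.4–77.1; the original method is
  unstated, so only the DOR point estimate is contract-bound.

Zero cells: a zero *denominator* cell makes the ratio infinite — the value
is flagged `infinite` and its interval computed from Haldane–Anscombe
continuity-corrected cells (+0.5 everywhere); a zero *numerator* cell keeps
its well-defined raw estimate with a corrected interval and the
`zero_cell_corrected` flag. Zero margins flag the affected metric
`undefined`. Report formatting follows the published precision:
percentages and LR+/DOR to one decimal, LR− to two; non-estimable entries
print `NE`.

One further reproduction caveat: on the reconstructed cardiovascular row
(24/172) the exact lower sensitivity bound is 9.149% → 9.1, while the
source prints 9.2 (Wilson would give 9.6). Every other figure of that row
reproduces exactly, so the package reports the exact-method value.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not renal
physiology. Per patient it draws sex (46.8% male), age (normal 61.8 ± 15.9
truncated to 18–95), an eGFR stratum (73.7 / 24.5 / 1.9% across ≥60,
30–59.9, 15–29.9), admission type (1.5% emergent), and surgery category
(9.6% cardiovascular; the ten other fee-schedule categories weighted by
their cohort frequencies). A target eGFR sampled inside the stratum (kept
off the 15/30/60 boundaries) is inverted in closed form to a baseline SCr,
capped at 3.7 mg/dL so no generated patient trips the high-baseline
exclusion; outpatient series (Poisson-distributed count, mean 3, minimum
1) scatter multiplicatively within ±3% so the realized mean stays in
stratum and above eGFR 15.

AKI is assigned per (surgery × admission) cell; the default incidences
(7.2 / 22.9 / 24.8 / 81.0% for non-CV-planned, CV-planned, non-CV-emergent,
CV-emergent) were chosen so the implied margins reproduce the reported
overall (9.0%), cardiovascular (24%), and emergent (31%) prevalences. The
stage mix defaults to 504:82:77 and coding behavior to stage-dependent
sensitivity (6/504, 21/159, 21/159) with specificity 6703/6711, the values
implied by the published stage-restricted row; 48/77 of stage-3 cases
receive a post-operative dialysis code.

**Margin construction.** With `noise_margin` m (default 0.1), non-AKI
trajectories drift within ±min(0.2, 0.5−1.5m, 0.3(1−m)/2B) of the realized
baseline B, which bounds them strictly below every rule; AKI trajectories
peak on post-operative day 1 or 2 strictly inside their stage band —
relative peaks at ratios in [band_lo·(1+m/3), band_hi·(1−m/3)] capped at
4(1−m)/B so stage-1/2 cases cannot trip the SCr ≥ 4 promotion, absolute
stage-1 peaks at B + 0.3(1+m) (used only when it stays below 1.5(1−m)·B),
and RRT cases carry a rule-violating trajectory plus a dialysis code. When
a high baseline makes any clean stage-1/2 trajectory impossible (peak would
cross 4 mg/dL even with margin — rare eGFR ≈ 15–20 draws), the latent truth
is promoted to stage 3 rather than emit an inconsistent record. These
margins are what make the round-trip guarantee exact: the phenotyper
recovers the latent stage for 100% of generated patients at any seed.

Stage-1 cases alternate between the absolute and relative trigger so both
branches of the definition are exercised. Planned admissions have surgery
on day 1–3 and one pre-operative inpatient SCr the day before surgery, so
the latest-inpatient baseline variant has qualifying data; the exact
round-trip guarantee applies to the main (mean-outpatient) baseline, under
which the trajectories are constructed.

`allocation="expected"` replaces Bernoulli draws for incidence, stage mix
and coding with deterministic largest-remainder counts — a fixed-margin
design used to build cohorts whose 2×2 matches a target exactly (the
end-to-end report-reproduction test relies on it). `inject_exclusions`
mutates disjoint random patients to trigger each attrition criterion a
requested number of times.

What the generator does *not* model — and what passing tests therefore do
not establish about real data: creatinine autocorrelation and measurement
error beyond threshold placement, nephrotoxin exposure, borderline values
at rule thresholds, coding that depends on anything but true stage, and
cross-admission correlation. The round-trip tests validate the *logic* of
the pipeline, not the clinical performance of coding.

## Pipeline and reproducibility

A run is one `RunConfig` (YAML-serializable): either a simulation config or
a directory with the four CSV tables, plus the baseline method, detection
window, code set, minimum reference stage, stratifiers and seed. All
randomness flows from the single run seed. Outputs are the attrition
table, per-case adjudications, the report in CSV (printed precision) and
JSON (full precision with flags), and a manifest with package/library
versions, row counts and a SHA-256 hash per file; identical config+seed
reproduce every byte. The sensitivity suite reuses one simulated/loaded
cohort for the main analysis and the four variants.

Problem sizes used by the test suite and the acceptance script — 1,000
random oracle fixtures, 2,000 coverage replicates at n = 500, and one
synthetic cohort of 7,374 — were chosen to match the validation layers'
purposes (exhaustive small-fixture checking, Monte-Carlo error ≈ 0.5
percentage points, and the study-scale cohort) while keeping a full run in
well under a minute of compute.

## Limitations

* Urine-output KDIGO criteria are out of scope (the data the package
  models do not record them), as are pediatric and non-Japanese eGFR
  equations.
* The eligibility attrition *ordering* is a reporting convention; only the
  final cohort is contract-bound.
* The DOR interval method and the one-digit cardiovascular CI discrepancy
  are documented above; neither affects point estimates.
* Identifiers are per-hospitalization: repeat admissions of one patient
  are independent analysis units, and no cross-hospital linkage is
  attempted.
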