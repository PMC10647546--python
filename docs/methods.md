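# Methods

## The screening model

The screen under evaluation is a daily, patient-centered rule embedded
in the EMR. Its elements are binary predicates of routinely recorded
data; the screen result is their disjunction (OR): a patient is flagged
the moment any single element fires. Formally, for element vector
`x ∈ {0,1}^K` and active subset `S`, the prediction is
`ŷ = 1[ Σ_{j∈S} x_j > 0 ]`. OR aggregation makes the rule monotone:
enlarging `S` can only raise sensitivity and lower specificity, which
is the central trade-off all evaluation output exposes.

Element thresholds follow the screen's definitions: two or more food
allergies (≥ 2); anthropometric z strictly below −1, using
weight-for-length below two years corrected age and BMI-for-age at two
years and above (the two are mutually exclusive by age and are merged
into one analysis variable); the three status-change elements require
their condition to hold on at least three consecutive most-recent days.
Where the source descriptions of thresholds are internally inconsistent
("2+" vs "> 2" allergies, "≥ 5%" vs "> 5%" weight loss, "≥ 3" vs "> 3"
NPO days), this package follows the methods-style wording (≥ 2, ≥ 5%,
≥ 3) and notes the ambiguity here; the conflict is unresolvable from
the published text alone.

The weight-loss element needs a baseline the source never defines. We
use the highest weight recorded in the current admission, recomputed
daily: it is conservative (flags loss from the in-stay peak, not only
from admission), reproducible, and insensitive to admission-day fluid
status. The per-day condition is a drop of ≥ 5% from that running peak;
the element fires when the condition holds on ≥ 3 consecutive days.

The status-change cadence is hospital day 4 (admission day = day 1)
followed by every Monday, Wednesday and Friday; an evaluation "sees"
only completed days (the 06:00 run on day d uses days 1..d−1). An
off-schedule evaluation raises an error, or proceeds with a warning in
permissive mode.

Growth-reference z-scores use the LMS parameterization,
`z = ((x/M)^L − 1)/(L·S)` with the log-limit at `L = 0` (applied for
|L| ≤ 1e-12; the two branches then agree far below reporting
precision). Reference rows are caller-supplied; no growth tables ship
with the package. Missing anthropometry yields a negative flag plus a
logged warning rather than an error, because an automated daily screen
cannot halt on a missing vital.

The PNST and the dietitian-risk element are subjective or externally
validated inputs; the engine consumes them as opaque booleans and never
infers them.

## Diagnostic accuracy

Confusion counts are stored by the full four-level severity scale
(none/mild/moderate/severe); a dichotomy — *any malnutrition* or
*moderate/severe only* (none + mild grouped as negative) — collapses
them only at metric time. Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN); a zero denominator
makes the metric `None`, never 0 or 1. No confidence intervals are
produced (the evaluation design this mirrors reported none).

Per-element association uses the two-sided Fisher exact test with the
"probability no greater than observed" convention of mainstream
statistical software (implemented via scipy); the test suite and
acceptance script verify it against a brute-force exact-rational
hypergeometric enumeration on every 2×2 table with total ≤ 30.

## Penalty-weighted subset selection

A screen that misses severe malnutrition is worse than one that
over-flags, so each candidate subset's predictions are charged
`1·FN_mild + 3·FN_moderate + 5·FN_severe + 0.2·FP_none` (any-malnutrition
mode). In moderate/severe-only mode mild cases join the negative class:
`3·FN_moderate + 5·FN_severe + 0.2·(FP_none + FP_mild)`. The miss
weights 3 and 5 are retained and the false-positive weight extends to
flagged mild patients — the minimal consistent extension of the
grouping; all four weights are configurable.

The prediction rule for a subset is the OR of its elements, matching
the screen's own any-positive semantics. The search is exhaustive over
all `2^K − 1` nonempty subsets (capped at K = 20; beyond that the
function refuses rather than silently approximating). The three
status-change elements are excluded from the default vocabulary — they
fire too rarely to inform selection — and can be re-admitted by flag.
Ties are never broken silently: all subsets within 1e-9 of the per-size
or global minimum are reported, ordered lexicographically by element
name, so output is deterministic and order-invariant.

Reported scores are raw penalty units (unnormalized); metrics print at
three decimals and scores at one, matching the field's table style.

## Synthetic cohort generator

Patient-level data for this evaluation were never released; the
generator emulates the published cohort's statistical skeleton and is
the study condition for every cohort-level result:

- **Strata.** 250 assessed + 918 unassessed patients by default.
- **Severity.** Assessed severity is multinomial with probabilities
  181/250, 27/250, 24/250, 18/250 (72.4/10.8/9.6/7.2%). Unassessed
  patients carry the sentinel `unknown`, distinct from `none`.
- **Elements.** Drawn Bernoulli conditional on the malnutrition
  dichotomy only — the published stratified counts condition on that
  dichotomy, not on severity grade; per-grade rates are an optional
  override. Default rates are the exact published fractions (e.g. PN
  29/181 | no malnutrition, 27/69 | any). Unassessed patients use the
  published marginal rates, including structural zeros for PN and
  dietitian-identified risk.
- **Dependence.** Optional: a per-patient standard-logistic latent
  factor enters every element's log-odds with loading
  `λ = sqrt(ρ/(1−ρ))`, so ρ is the latent share of logit variance.
  Because the published evidence is purely marginal, the default is
  ρ = 0 (independent elements). With ρ > 0 each element's intercept is
  solved numerically (quadrature + Brent root-finding, tolerance 1e-12)
  so configured marginal rates are preserved exactly. Any dependence
  structure here is a modeling choice, not an observed fact — the
  source reports no joint frequencies.
- **Ages.** Lognormal, clipped to [0.01, 17] years: assessed patients
  median 2 y (σ = 1.31, mean ≈ 4.7), unassessed median 4 y (σ = 0.97,
  mean ≈ 6.4), matching the published demographic summaries in median
  and roughly in mean. Ten percent of infants under two receive a
  prematurity correction of up to 16 weeks; corrected age never exceeds
  chronological age. Ages feed the anthropometric dispatch only and
  enter no calibrated quantity.
- **Seeding.** One master seed; stream k is
  `numpy.random.SeedSequence(seed, spawn_key=(k,))` with a fixed
  stream table (0 severity, 1/2 assessed latent/uniforms, 3 assessed
  ages, 4/5/6 unassessed), so adding a stratum never perturbs earlier
  draws and identical config + seed is bitwise reproducible.

What the generator does **not** emulate: within-stay severity dynamics
(severity is fixed per patient), admission/discharge processes, real
joint dependence between elements, and any element–age association.
Tests passing on synthetic cohorts therefore validate the *machinery*
(rule logic, counting, exact tests, search) and the generator's own
calibration — not the clinical performance of the screen on real
patients.

## Fixture expansion

The bundled stratified counts can be expanded into per-element
pseudo-cohorts whose 2×2 tables equal the counts exactly; positives are
assigned from the start of each stratum and severities in fixed blocks
(mild, moderate, severe). Joint structure across elements and between
element state and severity grade is deliberately not claimed; every
quantity computed from these pseudo-cohorts depends only on the
dichotomized margins, which are exact.

## Known irreproducibilities

Two published artifacts cannot be reproduced from the available
information, and this package does not attempt to match them:

- The numeric score/sensitivity/specificity columns of the published
  best-subset tables are inconsistent with the published element
  marginals (e.g. the anthropometric element alone shows 58.0%
  positivity among malnourished patients in the stratified table but a
  printed standalone sensitivity of 0.309), and the printed scores
  cannot be reconciled with the stated weights and cohort sizes.
- The published comparison table gives the admission instrument a
  standalone sensitivity of 10.0% where the stratified counts imply
  24/69 = 34.8%.

The implementation computes all metrics from counts by the standard
definitions; the selection *procedure* and the report *structure* are
validated by independent brute-force oracles and structural tests
instead of value matching.

## Problem sizes and numerical choices

Exhaustive selection runs 127 subsets on 250-patient cohorts (well
under a second). Generator calibration is verified at n = 100,000
within three binomial standard errors per rate. The Fisher enumeration
sweep covers all 46,375 tables with total ≤ 30. Tie tolerance in
selection is 1e-9 on penalty units; oracle agreement tolerances are
1e-12. Report percentages round to one decimal, with `0 (0%)`
special-cased for zero cells.
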