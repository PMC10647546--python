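# nutriscreen

Evaluation machinery for an EMR-embedded daily pediatric nutrition screen,
aimed at clinical-nutrition researchers and biostatisticians who want to
reproduce, stress-test or extend how such screens are validated in the
pediatric intensive care unit (PICU).

A hospital nutrition screen of this design combines an admission-time
nurse-administered instrument (the Pediatric Nutrition Screening Tool,
PNST, treated here as a single opaque boolean) with seven elements the
EMR derives automatically every day at 06:00 — enteral nutrition (EN),
parenteral nutrition (PN), intubation, 2+ food allergies, a merged
anthropometric flag (BMI-for-age z < −1 at corrected age ≥ 2 y,
weight-for-length z < −1 below 2 y), and a subjective dietitian-risk
flag — plus three status-change elements (intake < 50% of needs, NPO,
≥5% weight loss, each sustained ≥ 3 days) assessed on hospital day 4 and
every Monday/Wednesday/Friday. A patient screens positive when **any**
element is positive.

The package provides:

- **`nutriscreen.engine`** — the screening rule itself: element
  predicates, LMS (Box-Cox) growth-reference z-scores
  `z = ((x/M)^L − 1)/(L·S)`, the age-based anthropometric dispatch,
  consecutive-day streak logic, the Mon/Wed/Fri cadence, and OR
  aggregation over any element subset.
- **`nutriscreen.diagnostics`** — severity-stratified confusion counts,
  sensitivity/specificity/PPV/NPV (undefined ratios are `None`, never
  coerced), two-sided Fisher exact tests, and publication-style
  stratified contingency reports.
- **`nutriscreen.selection`** — cost-sensitive best-subset selection:
  every nonempty subset of daily elements is scored with a weighted
  misclassification penalty

  `score = 1·FN_mild + 3·FN_moderate + 5·FN_severe + 0.2·FP`,

  (in moderate/severe-only mode mild joins the negative class), and the
  lowest-score subset per size and overall is reported with full
  metrics, ties preserved.
- **`nutriscreen.cohort`** — a synthetic PICU cohort generator
  calibrated to the published strata: 250 assessed patients with
  severity split 181/27/24/18 (none/mild/moderate/severe) and element
  rates conditional on the malnutrition dichotomy, plus 918 unassessed
  patients, with optional latent-factor dependence between elements and
  fully documented seed streams. The original patient-level data were
  never released, so this generator defines the study conditions for
  all cohort-level analyses.
- **`nutriscreen.pipeline` / CLI** — an end-to-end driver emitting the
  report bundle with a content-hash manifest; identical config + seed
  gives a byte-identical bundle.

## Worked example

```python
import nutriscreen as ns
from nutriscreen.diagnostics import rows_to_text
from nutriscreen.selection import selection_report

cohort = ns.generate_cohort(ns.CohortConfig(seed=1))
res = ns.enumerate_models(cohort, mode="any_malnutrition")
print(rows_to_text(selection_report(res)))
```

prints (abbreviated to the first columns):

```
N  Score  Screening Variables                                           Sensitivity  Specificity
1  51.6   enteral_nutrition                                             0.845        0.201
2  39.6   enteral_nutrition, parenteral_nutrition                       0.915        0.173
3  34.4   anthropometric_flag, enteral_nutrition, parenteral_nutrition  0.972        0.151
4  34.0   anthropometric_flag, enteral_nutrition, parenteral_nutrition,
          pnst_positive                                                 0.986        0.134
...
```

Each row is the penalty-optimal subset of that size on this synthetic
cohort; the size-4 subset {anthropometric flag, EN, PN, PNST} attains
the global minimum score 34.0, meaning its missed cases and false
positives cost least under the 1/3/5/0.2 weighting. Larger subsets keep
sensitivity at 0.986 but erode specificity — the same
sensitivity-versus-specificity trade the screen exhibits in practice.

Running diagnostics on the bundled stratified counts instead
(`nutriscreen diagnostics --out-dir out/`) reproduces the published
contingency table exactly, e.g. PN positive in 27/69 (39.1%) of
malnourished vs 29/181 (16.0%) of non-malnourished patients, Fisher
p < 0.001, and an any-positive-screen rate of 243/250 (97.2%).

The same operations are available from the shell:

```
nutriscreen simulate --seed 1 --out cohort.csv
nutriscreen select --cohort cohort.csv --mode moderate_severe --out sel.tsv
nutriscreen run --seed 1 --out bundle/
```

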