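# glimcrp

Nutritional assessment of critically ill patients combines the GLIM (Global
Leadership Initiative on Malnutrition) phenotypic criteria — here, the Asian
low-BMI thresholds (BMI < 18.5 kg/m² under 70 years, < 20 at ≥ 70 years) —
with an etiologic inflammation criterion. C-reactive protein (CRP) is the
cheap, universally available inflammation marker, but it peaks around 36 h
after an insult, so the admission-day value can understate the inflammatory
burden. `glimcrp` implements a claims-database analysis of that problem for
ICU cohorts:

1. screen emergent ICU admissions (age ≥ 18, ≥ 3 consecutive ICU days,
   ≥ 5 hospital days, BI/BMI/age recorded, ≥ 1 CRP value in the first week),
   and group them into eight diagnosis categories from ICD-10 code ranges;
2. linearly interpolate missing CRP on hospital days 0–2 from the values
   observed on days 0–6, and compute three windowed statistics: CRP(day 0),
   max CRP(days 0–1), max CRP(days 0–2);
3. for the composite outcome (in-hospital death ∨ Barthel index < 60 at
   discharge ∨ length of stay ≥ 14 days), build ROC curves for each window —
   overall and per diagnosis subgroup, in the all-case and complete-case
   populations — and select the optimal cut-off c\* maximising the Youden
   index J = sensitivity + specificity − 1;
4. cross-classify patients as CRP± (max CRP(d0–2) > c\*) × BMI± (GLIM
   low-BMI) and compare outcomes across the four groups with the
   Kruskal–Wallis test and Conover–Iman pairwise post hoc tests (raw and
   Bonferroni-adjusted);
5. score severity with a claims-adapted SOFA (respiratory component graded
   by support level, cardiovascular component 0 without catecholamines) and
   the catecholamine index DOA + DOB + 100·NA + 100·AD (μg/kg/min).

Because the motivating data source (a proprietary Japanese DPC claims
database) is not distributable, the package ships a synthetic cohort
generator (`glimcrp.synthetic_cohort`) that emulates its schema and the
statistical structure the analysis assumes — diagnosis-dependent CRP
kinetics, per-day measurement missingness, and outcomes driven by a planted
logistic model on max CRP, low BMI and age — so the entire pipeline is
testable and reproducible offline.

Audience: biostatisticians and intensive-care researchers who want to
replicate or stress-test CRP-based GLIM inflammation criteria on their own
cohort tables, or to study the method's behaviour under known data-generating
mechanisms.

## Worked example

```bash
glimcrp simulate --n 20000 --seed 1 --out cohort.csv
glimcrp analyze --input cohort.csv --outdir demo
glimcrp report --outdir demo
```

prints (elided):

```
Attrition flow:
  screened: 20000
  ...
  excluded: 4200
  included: 15800

All-diagnoses AUC (day 0 / days 0-1 / days 0-2): 0.59 / 0.59 / 0.60
Optimal CRP cut-off (d02): 3.79 mg/dL

Four-group outcomes:
  crp_pos_bmi_pos (n=1710): in-hospital mortality 27.4%, BI<60 66.0%, LOS>=14 82.2%
  crp_neg_bmi_pos (n=2234): in-hospital mortality 8.0%, BI<60 58.7%, LOS>=14 76.6%
  crp_pos_bmi_neg (n=5112): in-hospital mortality 19.3%, BI<60 46.6%, LOS>=14 80.4%
  crp_neg_bmi_neg (n=6744): in-hospital mortality 4.5%, BI<60 37.5%, LOS>=14 71.9%
```

Reading the output: 79% of the simulated admissions survive screening; the
widest CRP window (days 0–2) discriminates the composite outcome best, as it
is the quantity the planted outcome model actually uses; the Youden-optimal
cut-off lands near 3.8 mg/dL under the default generator conditions; and the
four GLIM groups separate cleanly, with in-hospital mortality ordered
CRP+BMI+ > CRP+BMI− > CRP−BMI+ > CRP−BMI−, i.e. the inflammation criterion
carries more of the mortality signal than low BMI alone, while both together
mark the highest-risk group. `demo/` also contains the stratified AUC table
(`table1_auc.csv`), per-group characteristics and outcome tables, the
long-format Conover p-values, and a ROC point dump for plotting.

The same pipeline runs on any cohort CSV with the documented schema (one row
per admission, `crp_day0 … crp_day6` columns with empty cells for missing
measurements) — see `glimcrp analyze --help`.

## Package layout

| module             | contents                                                   |
|--------------------|------------------------------------------------------------|
| `synthetic_cohort` | `CohortSpec`, `generate_cohort`, `planted_truth`, CSV I/O  |
| `cohort_builder`   | eligibility rules, attrition table, ICD-10 categorisation  |
| `severity`         | modified SOFA components, catecholamine index              |
| `crp_features`     | CRP interpolation and windowed statistics                  |
| `outcomes_glim`    | outcome flags, GLIM low-BMI rule, four-group labels        |
| `roc_stats`        | ROC curves, AUC, Youden cut-offs, stratified analysis      |
| `group_compare`    | Kruskal–Wallis, Conover–Iman post hoc, summary tables      |
| `pipeline` / `cli` | end-to-end orchestration and the `glimcrp` command         |

Methodological details, parameter defaults and known limitations are in
[`docs/methods.md`](docs/methods.md).
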