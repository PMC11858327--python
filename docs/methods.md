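# Methods

## The analysis

One row of input is one emergent ICU admission with demographics (age, sex,
BMI), an ICD-10 admission diagnosis, daily CRP (mg/dL) for hospital days 0–6
(day 0 = admission), respiratory support level, renal support and IABP
flags, day-1 mean catecholamine doses, four lab-based SOFA subscores, and
outcomes (in-hospital death and day of death, discharge Barthel index,
length of stay).

**Eligibility.** Included: age ≥ 18, emergent ICU admission, ≥ 3 consecutive
ICU days, ≥ 5 hospital days, Barthel index / BMI / age present, ≥ 1 CRP
measurement on days 0–6. All violated rules are recorded (not
short-circuited) so the attrition table reflects each rule's standalone
impact; consequently per-reason counts can sum to more than the number of
excluded patients. Whether "3 consecutive ICU days" counts day 0 as the
first day is delegated to whoever prepares `icu_consecutive_days`; the rule
applied is simply `icu_consecutive_days >= 3`.

**Diagnosis categories.** Sepsis (a dedicated flag, always wins),
neurology (I60–69, G00–99), cardiovascular (other I00–99), pulmonary (J),
metabolic (E), trauma (S, T00–19, T33–88, V, W, X, Y00–09), digestive
(K20–93), others. Matching uses the three-character category prefix. When an
admission carries several non-sepsis codes the *first* code in record order
decides — one admission has one admission diagnosis, and a deterministic
rule is required; within a single code the narrower neurology range is
tested before the cardiovascular range it overlaps.

**CRP features.** Missing days among {0, 1, 2} are filled by linear
interpolation between the nearest observed days anywhere in 0–6; a missing
day outside the observed range takes the nearest observed value (flat carry
— the degenerate case of linear interpolation, chosen over extrapolated
slopes, which would manufacture trends from noise). Observed values are
never altered. Features: CRP(day 0), max over days 0–1, max over days 0–2.
A *complete case* has measured (not imputed) CRP on all of days 0–2; the
*all-case* population is everyone eligible.

**ROC / Youden.** Thresholds sweep the distinct observed score values
(positive call: score ≥ threshold), plus a sentinel at +∞; tied scores enter
the call together, so the trapezoidal AUC equals the Mann–Whitney
pair-counting probability with ties counted ½ (asserted to 1e-12 in tests).
Observed values are used as candidate cut-offs (rather than midpoints) so a
reported cut-off is always an attainable measurement. The optimal cut-off
maximises J = sens + spec − 1 over non-sentinel thresholds; ties (detected
with a 1e-12 tolerance, since equal J values assembled from different
sens/spec pairs can differ by an ulp) break toward the *smaller* cut-off,
favouring sensitivity in a screening context. The stratified analysis
produces one report per population {all-case, complete-case} × window
{day 0, days 0–1, days 0–2} × subgroup {all + 8 categories} (54 cells); the
cut-off is reported only for the window with the highest AUC in each
population × subgroup row (AUC ties break toward the wider window). Strata
with a single outcome class are flagged undefined instead of raising.

**Four-group classification.** CRP+ means max CRP(days 0–2) strictly
greater than the cut-off (the strict form is the documented classification
rule; the ROC sweep's internal "≥" convention is a separate choice and the
two are deliberately not conflated). BMI+ is the GLIM Asian low-BMI rule:
BMI < 18.5 under 70 years, < 20 at ≥ 70 years, with age exactly 70 using the
≥ 70 threshold. By default the cut-off used for classification is the
Youden optimum from the all-case, all-diagnoses, days 0–2 window; a fixed
cut-off can be supplied instead.

**Outcomes.** Composite = in-hospital death ∨ BI < 60 (strict) ∨ LOS ≥ 14.
Secondary: 14- and 28-day mortality (death day ≤ K), BI and LOS as
continuous variables.

**Group comparison.** All outcomes — binary flags included — are compared
with the tie-corrected Kruskal–Wallis H (χ² approximation, k−1 df), followed
by Conover–Iman pairwise tests on the pooled mid-ranks:

t_ij = (R̄_i − R̄_j) / √( S² · (N−1−H)/(N−k) · (1/n_i + 1/n_j) ),

with S² the pooled-rank variance and two-sided p from Student's t on N−k
df (the H-corrected Conover–Iman form). Raw and Bonferroni-adjusted
(× k(k−1)/2, capped at 1) matrices are both reported, because with six
pairwise tests the adjustment choice flips borderline p-values (e.g. 0.04);
the significance threshold α (default 0.05, applied to adjusted values) is
configuration, not code. If every group is identical the tie correction
degenerates and H is defined as 0 (p = 1); under perfect separation the
variance factor reaches 0 and pairwise p-values collapse to 0/1 by rank-mean
difference.

## The synthetic cohort generator

The generator emulates the claims-data features the analysis depends on;
its defaults describe a large Japanese emergent-ICU population.

* **Demographics.** Age ~ Normal(73.1, 14.5) clipped to [18, 105] and
  rounded; 58.8% male; BMI ~ Normal(22.5, 4.6) clipped to [12, 45] —
  yielding ~25% GLIM-low-BMI. Diagnosis mix (sepsis 11.4%, cardiovascular
  24.6%, pulmonary 6.4%, metabolic 2.0%, neurology 27.5%, trauma 7.5%,
  digestive 4.9%, others 15.7%), a neurology-heavy emergent case mix.
* **CRP kinetics.** Per category, a patient-level peak log-CRP ~
  Normal(μ_cat, 0.8) with μ ranging from 0.0 (neurology, ≈ 1 mg/dL) to 2.7
  (sepsis, ≈ 15 mg/dL); log-CRP rises linearly at 0.45/day to a peak at day
  1.5 (CRP peaks ≈ 36 h after insult) and decays at 0.12/day afterwards,
  with independent Normal(0, 0.25) day-level noise on the log scale —
  piecewise log-linear with multiplicative noise, the fewest parameters that
  give the right qualitative shape. Values are rounded to 0.01 mg/dL.
* **Missingness.** Each day's measurement is censored independently with
  probability 0.316, so (1 − 0.316)³ ≈ 32% of patients are complete cases —
  the complete-case share reported for the motivating database. If all seven
  days would be censored, the day with the smallest censoring draw is kept
  so eligible rows remain analysable.
* **Outcomes.** For each of death, BI < 60 and LOS ≥ 14:
  logit p = β₀ + β₁·maxCRP(d0–2, uncensored) + β₂·1[low BMI] +
  β₃·(age−70)/10. Defaults: death (−3.3, 0.12, 0.5, 0.25), BI < 60 (−0.75,
  0.035, 0.8, 0.45), LOS ≥ 14 (0.85, 0.045, 0.25, 0.05) — sized analytically
  so overall mortality runs ~12% with the CRP effect dominating low BMI for
  mortality and prolonged stay, and low BMI dominating for poor discharge
  function, the qualitative pattern the four-group comparison is meant to
  exhibit. LOS is 14 + Geometric(0.10) − 1 when the long-stay flag fires,
  else uniform on 5–13; death day is Geometric(0.045) truncated at LOS
  (≈ 48% of deaths by day 14, ≈ 72% by day 28); BI is a flag-conditional
  truncated normal discretised to the 0–100 step-5 scale.
* **Interventions.** Support levels and device flags are independent
  categorical/Bernoulli draws at claims-plausible rates (MV 26.6%, ECMO
  3.4%, CHDF 3.4%, IHD 2.9%, IABP 4.0%); catecholamine doses are
  zero-inflated exponentials (noradrenaline 25% at mean 0.08 μg/kg/min,
  etc.); lab SOFA subscores are Binomial(4, 0.15).
* **Eligibility violations.** A configurable 21% of rows receive one
  uniformly chosen violation (minor age, non-emergent, short ICU stay, short
  hospital stay, missing BI, missing BMI, no CRP) to exercise screening.
* **Planted truth.** `planted_truth(spec)` replays the generator and
  returns the outcome coefficients and each patient's uncensored max CRP, so
  tests can verify effect recovery (AUC rises with β₁; mortality is monotone
  across true max-CRP quartiles; with all β = 0 the AUC is 0.5 and the
  marginal rates match the intercepts).

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real claims data: informative measurement (sicker
patients measured more often; censoring here is independent Bernoulli),
correlation between severity and interventions, non-logistic outcome
mechanisms, calendar-time effects, centre effects, and coding error. The
generator shares the analysis's functional form for outcomes, so planted-
effect tests demonstrate internal consistency and power, not external
validity. Numeric results (AUCs ≈ 0.60, cut-off ≈ 3.8 mg/dL under the
defaults) characterise the synthetic conditions, not any real population.

## Problem sizes

Simulation-based tests and the acceptance script use cohorts of 20 000
admissions — large enough that binomial noise on group percentages is well
under a point — with smaller cohorts (2 000–5 000) for structural checks,
and 2 000 permutations for the Conover null-calibration study. The whole
suite runs in well under a minute on one core.

## Numerical and degenerate-input choices

* Youden and AUC ties: see above (1e-12 tolerances; documented tie-breaks).
* A CRP series with no observations raises (upstream screening excludes it).
* Constant scores give a two-point ROC (sentinel + the single value), AUC
  0.5 and J = 0.
* `sens_spec_at` supports both strict (>) and non-strict (≥) calls at an
  external cut-off; the strict form matches the four-group rule, the
  non-strict form the ROC sweep.
* Kruskal–Wallis on identical pooled values returns H = 0, p = 1 rather
  than 0/0.
* Empty groups in the four-group comparison mark the affected outcome
  undefined (NaN statistics) instead of raising, since tiny subgroups are a
  routine feature of stratified claims analyses.

## Known limitations

* Only the low-BMI phenotypic criterion of GLIM is implemented; weight-loss
  and muscle-mass criteria are absent from claims data.
* The sepsis flag is an input; no ICD-10 sepsis code list is bundled.
* No confidence intervals on AUC and no between-window AUC tests (DeLong);
  the analysis reports point estimates only.
* The CRP cut-offs discovered on synthetic data depend on the planted
  kinetics and case mix; they are not clinical recommendations.
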