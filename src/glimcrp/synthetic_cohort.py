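"""Synthetic DPC-style ICU cohort generator.

The analyses in this package were designed for Japanese administrative
claims (DPC) data with laboratory values — a proprietary source.  This
module generates cohorts with the same schema and the statistical structure
the analysis assumes, so every downstream stage is testable end to end:

* one row per emergent ICU admission, with demographics, an ICD-10
  admission code per diagnosis category, daily CRP on hospital days 0-6,
  respiratory support level, renal support / IABP flags, day-1 mean
  catecholamine doses, four precomputed lab SOFA subscores, and outcomes;
* diagnosis-dependent CRP kinetics: each patient's log-CRP rises linearly
  from admission to a peak (CRP peaks around 36 h after an insult) and then
  decays, with multiplicative log-normal day-to-day noise;
* independent Bernoulli censoring of each daily CRP measurement;
* outcomes drawn from logistic models on the patient's *uncensored* maximum
  CRP over days 0-2, the GLIM low-BMI flag and age — the planted truth that
  parameter-recovery tests check against;
* a configurable fraction of records violating eligibility, to exercise the
  screening stage.

All randomness flows from ``CohortSpec.seed`` through a single
``numpy.random.default_rng`` stream, so a given spec always produces a
byte-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cohort_builder import DiagnosisCategory
from .crp_features import CRP_COLUMNS, CrpSeries
from .severity import LAB_COMPONENTS, CatecholamineDoses, OxygenSupport

CATEGORIES = tuple(c.value for c in DiagnosisCategory)

#: Representative ICD-10 admission codes per category.  Sepsis admissions
#: additionally carry the sepsis flag, which takes precedence anyway.
_CODE_POOLS: dict[str, tuple[str, ...]] = {
    "sepsis": ("A41.9", "A40.3"),
    "cardiovascular": ("I21.9", "I50.0", "I71.3"),
    "pulmonary": ("J18.9", "J96.0", "J69.0"),
    "metabolic": ("E11.1", "E87.2"),
    "neurology": ("I63.9", "I61.9", "G41.0"),
    "trauma": ("S06.5", "T07", "V89.2"),
    "digestive": ("K65.0", "K92.2", "K85.9"),
    "others": ("N17.9", "C80.9", "R57.8"),
}

_DRUGS = ("dopamine", "dobutamine", "noradrenaline", "adrenaline")

#: Cohort CSV column order.
COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "icd10_codes",
    "has_sepsis_code",
    "emergent_admission",
    "icu_consecutive_days",
    "hospital_los_days",
    "died_in_hospital",
    "death_day",
    "barthel_index",
    *CRP_COLUMNS,
    "oxygen_support",
    "chdf",
    "ihd",
    "iabp",
    *_DRUGS,
    *(f"sofa_{c}" for c in LAB_COMPONENTS),
)


class CrpKinetics(BaseModel):
    """Per-category CRP trajectory parameters (log scale, natural log)."""

    log_peak_mean: float
    log_peak_sd: float = Field(ge=0)
    peak_day: float = Field(ge=0, le=6, default=1.5)
    rise_rate: float = Field(ge=0, default=0.45)
    decay_rate: float = Field(ge=0, default=0.12)
    noise_sd: float = Field(ge=0, default=0.25)


class OutcomeCoefficients(BaseModel):
    """Logistic model logit(p) = intercept + beta_maxcrp*maxCRP(d0-2)
    + beta_lowbmi*1[low BMI] + beta_age*(age-70)/10."""

    intercept: float
    beta_maxcrp: float
    beta_lowbmi: float
    beta_age: float


class OutcomeModel(BaseModel):
    death: OutcomeCoefficients
    bi_lt_60: OutcomeCoefficients
    los_ge_14: OutcomeCoefficients


class InterventionRates(BaseModel):
    oxygen_support: dict[str, float]
    chdf: float = Field(ge=0, le=1)
    ihd: float = Field(ge=0, le=1)
    iabp: float = Field(ge=0, le=1)
    catecholamine_prob: dict[str, float]
    catecholamine_mean_dose: dict[str, float]

    @field_validator("oxygen_support")
    @classmethod
    def _oxygen_probs(cls, v: dict[str, float]) -> dict[str, float]:
        levels = {lvl.value for lvl in OxygenSupport}
        if set(v) != levels:
            raise ValueError(f"oxygen_support must give a probability for {sorted(levels)}")
        if any(not 0 <= p <= 1 for p in v.values()):
            raise ValueError("oxygen_support probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("oxygen_support probabilities must sum to 1")
        return v

    @field_validator("catecholamine_prob")
    @classmethod
    def _drug_probs(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(_DRUGS):
            raise ValueError(f"catecholamine_prob must cover {_DRUGS}")
        if any(not 0 <= p <= 1 for p in v.values()):
            raise ValueError("catecholamine_prob values must lie in [0, 1]")
        return v

    @field_validator("catecholamine_mean_dose")
    @classmethod
    def _drug_doses(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(_DRUGS):
            raise ValueError(f"catecholamine_mean_dose must cover {_DRUGS}")
        if any(d < 0 for d in v.values()):
            raise ValueError("catecholamine_mean_dose values must be >= 0")
        return v


class NormalDist(BaseModel):
    mean: float
    sd: float = Field(ge=0)


def _default_diagnosis_mix() -> dict[str, float]:
    # Neurology-heavy emergent ICU case mix typical of Japanese claims data.
    return {
        "sepsis": 0.114,
        "cardiovascular": 0.246,
        "pulmonary": 0.064,
        "metabolic": 0.020,
        "neurology": 0.275,
        "trauma": 0.075,
        "digestive": 0.049,
        "others": 0.157,
    }


def _default_kinetics() -> dict[str, CrpKinetics]:
    # Peak log-CRP levels per category: septic and digestive (peritonitis,
    # pancreatitis) admissions run high; strokes and seizures run low.
    peak_means = {
        "sepsis": 2.7,
        "cardiovascular": 1.1,
        "pulmonary": 1.9,
        "metabolic": 1.1,
        "neurology": 0.0,
        "trauma": 1.5,
        "digestive": 2.2,
        "others": 1.5,
    }
    return {
        cat: CrpKinetics(log_peak_mean=mu, log_peak_sd=0.8)
        for cat, mu in peak_means.items()
    }


def _default_outcome_model() -> OutcomeModel:
    # Sized so that in-hospital mortality runs ~12% overall with the
    # CRP effect dominating the low-BMI effect for mortality and LOS, and
    # the low-BMI effect dominating for poor discharge function (BI < 60).
    return OutcomeModel(
        death=OutcomeCoefficients(
            intercept=-3.3, beta_maxcrp=0.12, beta_lowbmi=0.5, beta_age=0.25
        ),
        bi_lt_60=OutcomeCoefficients(
            intercept=-0.75, beta_maxcrp=0.035, beta_lowbmi=0.8, beta_age=0.45
        ),
        los_ge_14=OutcomeCoefficients(
            intercept=0.85, beta_maxcrp=0.045, beta_lowbmi=0.25, beta_age=0.05
        ),
    )


def _default_interventions() -> InterventionRates:
    return InterventionRates(
        oxygen_support={
            "none": 0.35,
            "oxygen": 0.29,
            "nppv_or_hfnc": 0.06,
            "mechanical_ventilation": 0.266,
            "ecmo": 0.034,
        },
        chdf=0.034,
        ihd=0.029,
        iabp=0.04,
        catecholamine_prob={
            "dopamine": 0.05,
            "dobutamine": 0.05,
            "noradrenaline": 0.25,
            "adrenaline": 0.02,
        },
        catecholamine_mean_dose={
            "dopamine": 3.0,
            "dobutamine": 3.0,
            "noradrenaline": 0.08,
            "adrenaline": 0.05,
        },
    )


class CohortSpec(BaseModel):
    """Everything that determines a synthetic cohort.

    Defaults emulate a large Japanese emergent-ICU claims cohort: mean age
    ~73, ~59% male, mean BMI ~22.5, a neurology-heavy diagnosis mix, and a
    per-day CRP missingness of 0.316 so that (1-p)^3 ~ 32% of patients are
    complete cases on days 0-2.
    """

    n_patients: int = Field(ge=1)
    seed: int = 0
    diagnosis_mix: dict[str, float] = Field(default_factory=_default_diagnosis_mix)
    crp_kinetics: dict[str, CrpKinetics] = Field(default_factory=_default_kinetics)
    missingness_prob: float = Field(ge=0, le=1, default=0.316)
    outcome_model: OutcomeModel = Field(default_factory=_default_outcome_model)
    age_dist: NormalDist = Field(default_factory=lambda: NormalDist(mean=73.1, sd=14.5))
    bmi_dist: NormalDist = Field(default_factory=lambda: NormalDist(mean=22.5, sd=4.6))
    sex_ratio: float = Field(ge=0, le=1, default=0.588)  # fraction male
    intervention_rates: InterventionRates = Field(default_factory=_default_interventions)
    ineligible_fraction: float = Field(ge=0, le=1, default=0.21)
    death_day_geom_p: float = Field(gt=0, le=1, default=0.045)
    los_tail_geom_p: float = Field(gt=0, le=1, default=0.10)

    @field_validator("diagnosis_mix")
    @classmethod
    def _mix(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(CATEGORIES):
            raise ValueError(f"diagnosis_mix must cover {CATEGORIES}")
        if any(not 0 <= p <= 1 for p in v.values()):
            raise ValueError("diagnosis_mix probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("diagnosis_mix must sum to 1 within 1e-9")
        return v

    @model_validator(mode="after")
    def _kinetics_cover_categories(self) -> "CohortSpec":
        if set(self.crp_kinetics) != set(CATEGORIES):
            raise ValueError(f"crp_kinetics must cover {CATEGORIES}")
        return self


@dataclass(frozen=True)
class PatientRecord:
    """One admission, in the record form the scalar operations work on."""

    patient_id: str
    age: float | None
    sex: str
    bmi: float | None
    icd10_codes: list[str]
    has_sepsis_code: bool
    emergent_admission: bool
    icu_consecutive_days: int
    hospital_los_days: int
    died_in_hospital: bool
    death_day: int | None
    barthel_index: int | None
    crp: CrpSeries
    oxygen_support: str
    chdf: bool
    ihd: bool
    iabp: bool
    catecholamine_doses: CatecholamineDoses
    lab_subscores: dict[str, int]

    @classmethod
    def from_row(cls, row: pd.Series) -> "PatientRecord":
        def opt(v):
            return None if pd.isna(v) else v

        return cls(
            patient_id=str(row["patient_id"]),
            age=opt(row["age"]),
            sex=str(row["sex"]),
            bmi=opt(row["bmi"]),
            icd10_codes=str(row["icd10_codes"]).split(";") if pd.notna(row["icd10_codes"]) and row["icd10_codes"] else [],
            has_sepsis_code=bool(row["has_sepsis_code"]),
            emergent_admission=bool(row["emergent_admission"]),
            icu_consecutive_days=int(row["icu_consecutive_days"]),
            hospital_los_days=int(row["hospital_los_days"]),
            died_in_hospital=bool(row["died_in_hospital"]),
            death_day=None if pd.isna(row["death_day"]) else int(row["death_day"]),
            barthel_index=None if pd.isna(row["barthel_index"]) else int(row["barthel_index"]),
            crp=CrpSeries(row[list(CRP_COLUMNS)].to_numpy(float)),
            oxygen_support=str(row["oxygen_support"]),
            chdf=bool(row["chdf"]),
            ihd=bool(row["ihd"]),
            iabp=bool(row["iabp"]),
            catecholamine_doses=CatecholamineDoses(
                **{d: float(row[d]) for d in _DRUGS}
            ),
            lab_subscores={c: int(row[f"sofa_{c}"]) for c in LAB_COMPONENTS},
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Generation-time ground truth for parameter-recovery tests."""

    outcome_model: OutcomeModel
    patient_id: np.ndarray
    true_max_crp_d02: np.ndarray  # uncensored maximum over days 0-2
    low_bmi: np.ndarray
    age: np.ndarray
    p_death: np.ndarray
    p_bi_lt_60: np.ndarray
    p_los_ge_14: np.ndarray


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _outcome_probability(
    coef: OutcomeCoefficients,
    max_crp: np.ndarray,
    low_bmi: np.ndarray,
    age: np.ndarray,
) -> np.ndarray:
    logit = (
        coef.intercept
        + coef.beta_maxcrp * max_crp
        + coef.beta_lowbmi * low_bmi.astype(float)
        + coef.beta_age * (age - 70.0) / 10.0
    )
    return _logistic(logit)


def _glim_low_bmi(bmi: np.ndarray, age: np.ndarray) -> np.ndarray:
    return np.where(age < 70, bmi < 18.5, bmi < 20.0)


_VIOLATIONS = (
    "age_lt_18",
    "not_emergent",
    "icu_lt_3",
    "los_lt_5",
    "missing_bi",
    "missing_bmi",
    "no_crp",
)


def _simulate(spec: CohortSpec) -> tuple[pd.DataFrame, PlantedTruth]:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # --- demographics and diagnosis -------------------------------------
    cat_idx = rng.choice(len(CATEGORIES), size=n, p=[spec.diagnosis_mix[c] for c in CATEGORIES])
    category = np.array(CATEGORIES)[cat_idx]
    age = np.clip(np.round(rng.normal(spec.age_dist.mean, spec.age_dist.sd, n)), 18, 105)
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    bmi = np.round(np.clip(rng.normal(spec.bmi_dist.mean, spec.bmi_dist.sd, n), 12.0, 45.0), 1)
    code_choice = rng.random(n)
    codes = np.array(
        [
            _CODE_POOLS[c][int(u * len(_CODE_POOLS[c]))]
            for c, u in zip(category, code_choice)
        ]
    )
    has_sepsis = category == "sepsis"

    # --- CRP trajectories -------------------------------------------------
    days = np.arange(7, dtype=float)
    log_crp = np.empty((n, 7))
    for ci, cat in enumerate(CATEGORIES):
        mask = cat_idx == ci
        if not mask.any():
            continue
        kin = spec.crp_kinetics[cat]
        peak = rng.normal(kin.log_peak_mean, kin.log_peak_sd, int(mask.sum()))
        offset = np.where(
            days <= kin.peak_day,
            -kin.rise_rate * (kin.peak_day - days),
            -kin.decay_rate * (days - kin.peak_day),
        )
        log_crp[mask] = peak[:, None] + offset[None, :]
    noise = np.empty((n, 7))
    for ci, cat in enumerate(CATEGORIES):
        mask = cat_idx == ci
        if mask.any():
            noise[mask] = rng.normal(0.0, spec.crp_kinetics[cat].noise_sd, (int(mask.sum()), 7))
    crp_true = np.round(np.exp(log_crp + noise), 2)
    true_max_d02 = crp_true[:, :3].max(axis=1)

    # --- outcomes from the planted logistic models ------------------------
    low_bmi = _glim_low_bmi(bmi, age)
    om = spec.outcome_model
    p_death = _outcome_probability(om.death, true_max_d02, low_bmi, age)
    p_bi = _outcome_probability(om.bi_lt_60, true_max_d02, low_bmi, age)
    p_los = _outcome_probability(om.los_ge_14, true_max_d02, low_bmi, age)
    died = rng.random(n) < p_death
    bi_low = rng.random(n) < p_bi
    los_long = rng.random(n) < p_los

    los = np.where(
        los_long,
        13 + rng.geometric(spec.los_tail_geom_p, n),
        rng.integers(5, 14, n),
    ).astype(int)
    death_draw = rng.geometric(spec.death_day_geom_p, n)
    death_day = np.where(died, np.minimum(death_draw, los), -1).astype(float)
    death_day[~died] = np.nan
    bi_latent = np.where(
        bi_low,
        np.clip(rng.normal(30.0, 25.0, n), 0.0, 55.0),
        np.clip(rng.normal(85.0, 15.0, n), 60.0, 100.0),
    )
    barthel = (np.round(bi_latent / 5.0) * 5).astype(float)
    icu_days = np.minimum(3 + rng.poisson(2.0, n), los).astype(int)

    # --- interventions and lab subscores ----------------------------------
    ir = spec.intervention_rates
    levels = [lvl.value for lvl in OxygenSupport]
    oxygen = np.array(levels)[
        rng.choice(len(levels), size=n, p=[ir.oxygen_support[l] for l in levels])
    ]
    chdf = rng.random(n) < ir.chdf
    ihd = rng.random(n) < ir.ihd
    iabp = rng.random(n) < ir.iabp
    doses = {}
    for drug in _DRUGS:
        on = rng.random(n) < ir.catecholamine_prob[drug]
        amount = rng.exponential(ir.catecholamine_mean_dose[drug] or 1.0, n)
        doses[drug] = np.round(np.where(on, amount, 0.0), 3)
    labs = {c: rng.binomial(4, 0.15, n) for c in LAB_COMPONENTS}

    # --- per-day measurement censoring ------------------------------------
    miss_u = rng.random((n, 7))
    missing = miss_u < spec.missingness_prob
    all_gone = missing.all(axis=1)
    if all_gone.any():
        # keep at least one measured day so eligible rows stay analysable
        keep = miss_u[all_gone].argmin(axis=1)
        missing[np.flatnonzero(all_gone), keep] = False
    crp_obs = np.where(missing, np.nan, crp_true)

    # --- planted eligibility violations ------------------------------------
    emergent = np.ones(n, dtype=bool)
    n_viol = int(round(spec.ineligible_fraction * n))
    if n_viol:
        viol_rows = rng.choice(n, size=n_viol, replace=False)
        viol_kind = rng.integers(0, len(_VIOLATIONS), n_viol)
        for row, kind_idx in zip(viol_rows, viol_kind):
            kind = _VIOLATIONS[kind_idx]
            if kind == "age_lt_18":
                age[row] = 16.0
            elif kind == "not_emergent":
                emergent[row] = False
            elif kind == "icu_lt_3":
                icu_days[row] = 2
            elif kind == "los_lt_5":
                los[row] = 4
                icu_days[row] = min(icu_days[row], 4)
                if died[row]:
                    death_day[row] = min(death_day[row], 4)
            elif kind == "missing_bi":
                barthel[row] = np.nan
            elif kind == "missing_bmi":
                bmi[row] = np.nan
            elif kind == "no_crp":
                crp_obs[row, :] = np.nan

    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    table = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "icd10_codes": codes,
            "has_sepsis_code": has_sepsis,
            "emergent_admission": emergent,
            "icu_consecutive_days": icu_days,
            "hospital_los_days": los,
            "died_in_hospital": died,
            "death_day": death_day,
            "barthel_index": barthel,
            **{col: crp_obs[:, d] for d, col in enumerate(CRP_COLUMNS)},
            "oxygen_support": oxygen,
            "chdf": chdf,
            "ihd": ihd,
            "iabp": iabp,
            **doses,
            **{f"sofa_{c}": labs[c] for c in LAB_COMPONENTS},
        },
        columns=list(COHORT_COLUMNS),
    )
    truth = PlantedTruth(
        outcome_model=om,
        patient_id=patient_id,
        true_max_crp_d02=true_max_d02,
        low_bmi=low_bmi,
        age=age.copy(),
        p_death=p_death,
        p_bi_lt_60=p_bi,
        p_los_ge_14=p_los,
    )
    return table, truth


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table with exactly ``spec.n_patients`` rows.

    Deterministic: identical specs (including the seed) give identical
    tables.
    """
    table, _ = _simulate(spec)
    return table


def planted_truth(spec: CohortSpec) -> PlantedTruth:
    """Ground truth (coefficients, uncensored max CRP) behind ``spec``'s cohort."""
    _, truth = _simulate(spec)
    return truth


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table; missing cells are left empty."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, restoring dtypes and validating the schema."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in COHORT_COLUMNS]
    if missing:
        raise ValueError(
            f"cohort CSV schema mismatch: missing columns {missing}"
            + (f"; unexpected columns {extra}" if extra else "")
        )
    for col in ("has_sepsis_code", "emergent_admission", "died_in_hospital", "chdf", "ihd", "iabp"):
        table[col] = table[col].astype(bool)
    return table


def expected_outcome_rate(coef: OutcomeCoefficients) -> float:
    """Marginal probability implied by the intercept alone (all betas zero)."""
    return 1.0 / (1.0 + math.exp(-coef.intercept))
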