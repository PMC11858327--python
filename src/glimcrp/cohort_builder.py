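"""Eligibility screening and diagnosis categorisation.

The study population is adults emergently admitted to the ICU who stayed in
the ICU for at least 3 consecutive days and in hospital for at least 5 days,
with Barthel index at discharge, BMI and age recorded and at least one CRP
measurement during the first week.  Admissions are grouped into eight
diagnosis categories from their ICD-10 admission codes, with a dedicated
sepsis flag taking precedence over any code-range match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .crp_features import CRP_COLUMNS


class DiagnosisCategory(str, Enum):
    SEPSIS = "sepsis"
    CARDIOVASCULAR = "cardiovascular"
    PULMONARY = "pulmonary"
    METABOLIC = "metabolic"
    NEUROLOGY = "neurology"
    TRAUMA = "trauma"
    DIGESTIVE = "digestive"
    OTHERS = "others"


#: Fixed order in which exclusion reasons are reported.
EXCLUSION_REASONS = (
    "age_lt_18",
    "not_emergent_icu",
    "icu_days_lt_3",
    "hospital_los_lt_5",
    "missing_bi",
    "missing_bmi",
    "missing_age",
    "no_crp_within_7_days",
)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[0-9A-Z]{1,4})?$")


@dataclass(frozen=True)
class EligibilityResult:
    included: bool
    exclusion_reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.included != (len(self.exclusion_reasons) == 0):
            raise ValueError("included must match an empty reason list")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value))


def apply_eligibility(record) -> EligibilityResult:
    """Screen one admission against every eligibility rule.

    All failing reasons are collected (no short-circuit) so an attrition
    report can count each rule's impact.  Absent fields become exclusion
    reasons rather than errors.
    """
    reasons = []
    age_missing = _is_missing(record.age)
    if not age_missing and record.age < 18:
        reasons.append("age_lt_18")
    if not record.emergent_admission:
        reasons.append("not_emergent_icu")
    if record.icu_consecutive_days < 3:
        reasons.append("icu_days_lt_3")
    if record.hospital_los_days < 5:
        reasons.append("hospital_los_lt_5")
    if _is_missing(record.barthel_index):
        reasons.append("missing_bi")
    if _is_missing(record.bmi):
        reasons.append("missing_bmi")
    if age_missing:
        reasons.append("missing_age")
    if record.crp.n_observed == 0:
        reasons.append("no_crp_within_7_days")
    return EligibilityResult(included=not reasons, exclusion_reasons=tuple(reasons))


def _classify_single_code(code: str) -> DiagnosisCategory:
    letter, number = code[0], int(code[1:3])
    # Neurology's I60-69 sits inside the cardiovascular I00-99 range, so the
    # narrower range is tested first.
    if (letter == "I" and 60 <= number <= 69) or letter == "G":
        return DiagnosisCategory.NEUROLOGY
    if letter == "I":
        return DiagnosisCategory.CARDIOVASCULAR
    if letter == "J":
        return DiagnosisCategory.PULMONARY
    if letter == "E":
        return DiagnosisCategory.METABOLIC
    if (
        letter == "S"
        or (letter == "T" and (number <= 19 or 33 <= number <= 88))
        or letter in "VWX"
        or (letter == "Y" and number <= 9)
    ):
        return DiagnosisCategory.TRAUMA
    if letter == "K" and 20 <= number <= 93:
        return DiagnosisCategory.DIGESTIVE
    return DiagnosisCategory.OTHERS


def categorize_diagnosis(
    icd10_codes: list[str], has_sepsis_code: bool
) -> DiagnosisCategory:
    """Map an admission's ICD-10 codes to one of the eight categories.

    A sepsis code always wins.  Otherwise the first code in record order
    decides; within a single code the narrower neurology range (I60-69,
    G00-99) is matched before the general cardiovascular range (I00-99).
    Ranges: pulmonary J00-99, metabolic E00-99, trauma S00-99 / T00-19 /
    T33-88 / V / W / X / Y00-09, digestive K20-93; anything else is others.
    """
    for code in icd10_codes:
        if not _CODE_RE.match(code):
            raise ValueError(f"malformed ICD-10 code: {code!r}")
    if has_sepsis_code:
        return DiagnosisCategory.SEPSIS
    if not icd10_codes:
        return DiagnosisCategory.OTHERS
    return _classify_single_code(icd10_codes[0])


# ---------------------------------------------------------------------------
# Frame-level screening


def eligibility_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-row boolean columns, one per exclusion reason, plus ``included``."""
    crp = cohort.loc[:, list(CRP_COLUMNS)]
    flags = pd.DataFrame(index=cohort.index)
    flags["age_lt_18"] = cohort["age"].notna() & (cohort["age"] < 18)
    flags["not_emergent_icu"] = ~cohort["emergent_admission"].astype(bool)
    flags["icu_days_lt_3"] = cohort["icu_consecutive_days"] < 3
    flags["hospital_los_lt_5"] = cohort["hospital_los_days"] < 5
    flags["missing_bi"] = cohort["barthel_index"].isna()
    flags["missing_bmi"] = cohort["bmi"].isna()
    flags["missing_age"] = cohort["age"].isna()
    flags["no_crp_within_7_days"] = crp.isna().all(axis=1)
    flags["included"] = ~flags[list(EXCLUSION_REASONS)].any(axis=1)
    return flags


def attrition_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Flowchart-style attrition counts: screened, per-reason, excluded, included."""
    flags = eligibility_frame(cohort)
    rows = [("screened", len(cohort))]
    rows += [(reason, int(flags[reason].sum())) for reason in EXCLUSION_REASONS]
    rows.append(("excluded", int((~flags["included"]).sum())))
    rows.append(("included", int(flags["included"].sum())))
    return pd.DataFrame(rows, columns=["stage", "count"])


def filter_included(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows passing every eligibility rule."""
    return cohort.loc[eligibility_frame(cohort)["included"]].reset_index(drop=True)


def add_diagnosis_category(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append a ``diagnosis_category`` column from codes and the sepsis flag."""
    categories = [
        categorize_diagnosis(
            codes.split(";") if codes else [], bool(sepsis)
        ).value
        for codes, sepsis in zip(
            cohort["icd10_codes"].fillna(""), cohort["has_sepsis_code"]
        )
    ]
    out = cohort.copy()
    out["diagnosis_category"] = categories
    return out
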