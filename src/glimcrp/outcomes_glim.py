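"""Outcome derivation and GLIM four-group classification.

The primary endpoint is a composite of in-hospital death, Barthel index
below 60 at discharge, and hospital stay of 14 days or more.  Patients are
cross-classified by the GLIM Asian low-BMI phenotypic criterion (BMI < 18.5
under 70 years, < 20 at 70 years or older) and an inflammation criterion
(maximum CRP over days 0-2 strictly above a cut-off) into four groups:
CRP+BMI+, CRP+BMI-, CRP-BMI+ and CRP-BMI-.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class FourGroup(str, Enum):
    CRP_POS_BMI_POS = "crp_pos_bmi_pos"
    CRP_POS_BMI_NEG = "crp_pos_bmi_neg"
    CRP_NEG_BMI_POS = "crp_neg_bmi_pos"
    CRP_NEG_BMI_NEG = "crp_neg_bmi_neg"


#: Display order used by the report tables (worst prognosis first).
GROUP_ORDER = (
    FourGroup.CRP_POS_BMI_POS,
    FourGroup.CRP_NEG_BMI_POS,
    FourGroup.CRP_POS_BMI_NEG,
    FourGroup.CRP_NEG_BMI_NEG,
)

OUTCOME_COLUMNS = (
    "in_hospital_death",
    "bi_lt_60",
    "los_ge_14",
    "composite",
    "death_by_day14",
    "death_by_day28",
)


@dataclass(frozen=True)
class OutcomeSet:
    in_hospital_death: bool
    bi_lt_60: bool
    los_ge_14: bool
    composite: bool
    death_by_day14: bool
    death_by_day28: bool
    bi: int
    los: int


def derive_outcomes(record) -> OutcomeSet:
    """Primary/composite and secondary outcomes for one patient.

    ``record`` needs ``died_in_hospital``, ``death_day``, ``barthel_index``
    and ``hospital_los_days``; missing BI or LOS is an upstream exclusion and
    raises here.
    """
    if record.barthel_index is None:
        raise ValueError("Barthel index missing; record should have been excluded")
    if record.hospital_los_days is None:
        raise ValueError("length of stay missing; record should have been excluded")
    death = bool(record.died_in_hospital)
    bi_low = record.barthel_index < 60
    los_long = record.hospital_los_days >= 14
    death_day = record.death_day if death else None
    return OutcomeSet(
        in_hospital_death=death,
        bi_lt_60=bi_low,
        los_ge_14=los_long,
        composite=death or bi_low or los_long,
        death_by_day14=death and death_day is not None and death_day <= 14,
        death_by_day28=death and death_day is not None and death_day <= 28,
        bi=int(record.barthel_index),
        los=int(record.hospital_los_days),
    )


def low_bmi_flag(bmi: float, age: float) -> bool:
    """GLIM Asian low-BMI criterion: <18.5 under 70 y, <20 at >=70 y."""
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    return bool(bmi < 18.5 if age < 70 else bmi < 20.0)


def four_group(low_bmi: bool, crp_max_d02: float, cutoff: float) -> FourGroup:
    """Cross-classify one patient; CRP+ means max CRP strictly above cut-off."""
    if cutoff <= 0:
        raise ValueError("CRP cut-off must be positive")
    crp_pos = crp_max_d02 > cutoff
    if crp_pos:
        return FourGroup.CRP_POS_BMI_POS if low_bmi else FourGroup.CRP_POS_BMI_NEG
    return FourGroup.CRP_NEG_BMI_POS if low_bmi else FourGroup.CRP_NEG_BMI_NEG


def add_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the outcome flag columns to an included-cohort table."""
    if cohort["barthel_index"].isna().any() or cohort["hospital_los_days"].isna().any():
        raise ValueError("BI or LOS missing; screen the cohort before deriving outcomes")
    out = cohort.copy()
    death = cohort["died_in_hospital"].astype(bool)
    dday = cohort["death_day"]
    out["in_hospital_death"] = death
    out["bi_lt_60"] = cohort["barthel_index"] < 60
    out["los_ge_14"] = cohort["hospital_los_days"] >= 14
    out["composite"] = out["in_hospital_death"] | out["bi_lt_60"] | out["los_ge_14"]
    out["death_by_day14"] = death & (dday <= 14)
    out["death_by_day28"] = death & (dday <= 28)
    return out


def add_four_group(cohort: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Append ``low_bmi`` and ``four_group`` columns (needs ``crp_max_d02``)."""
    if cutoff <= 0:
        raise ValueError("CRP cut-off must be positive")
    out = cohort.copy()
    low_bmi = np.where(
        cohort["age"] < 70, cohort["bmi"] < 18.5, cohort["bmi"] < 20.0
    )
    crp_pos = cohort["crp_max_d02"].to_numpy() > cutoff
    labels = np.where(
        crp_pos,
        np.where(low_bmi, FourGroup.CRP_POS_BMI_POS.value, FourGroup.CRP_POS_BMI_NEG.value),
        np.where(low_bmi, FourGroup.CRP_NEG_BMI_POS.value, FourGroup.CRP_NEG_BMI_NEG.value),
    )
    out["low_bmi"] = low_bmi
    out["four_group"] = labels
    return out


def four_group_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group outcome summary in the style of an outcomes table.

    Binary outcomes are reported as count and percentage; BI and LOS as
    median with interquartile range.
    """
    rows = []
    for group in GROUP_ORDER:
        sub = cohort.loc[cohort["four_group"] == group.value]
        n = len(sub)
        row: dict[str, object] = {"group": group.value, "n": n}
        for col in OUTCOME_COLUMNS:
            count = int(sub[col].sum()) if n else 0
            row[f"{col}_n"] = count
            row[f"{col}_pct"] = percent(count, n) if n else float("nan")
        for col, label in (("barthel_index", "bi"), ("hospital_los_days", "los")):
            if n:
                q1, med, q3 = sub[col].quantile([0.25, 0.5, 0.75])
                row[f"{label}_median"] = float(med)
                row[f"{label}_iqr_low"] = float(q1)
                row[f"{label}_iqr_high"] = float(q3)
            else:
                row[f"{label}_median"] = float("nan")
                row[f"{label}_iqr_low"] = float("nan")
                row[f"{label}_iqr_high"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage as printed in report tables: 100*count/total, rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)
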