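"""Modified SOFA score and catecholamine index from claims-style inputs.

Claims databases carry interventions and prescriptions but not blood-gas
values, so the respiratory SOFA component is graded from the level of
respiratory support instead of PaO2/FiO2, and the cardiovascular component
is 0 for any patient without catecholamines regardless of blood pressure.
The remaining four components (coagulation, liver, renal, CNS) arrive as
precomputed 0-4 subscores.  All doses are day-1 average rates in μg/kg/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class OxygenSupport(str, Enum):
    NONE = "none"
    OXYGEN = "oxygen"
    NPPV_OR_HFNC = "nppv_or_hfnc"
    MECHANICAL_VENTILATION = "mechanical_ventilation"
    ECMO = "ecmo"


_RESPIRATORY_SCORE = {
    OxygenSupport.NONE: 0,
    OxygenSupport.OXYGEN: 1,
    OxygenSupport.NPPV_OR_HFNC: 2,
    OxygenSupport.MECHANICAL_VENTILATION: 3,
    OxygenSupport.ECMO: 4,
}

LAB_COMPONENTS = ("coagulation", "liver", "renal", "cns")


@dataclass(frozen=True)
class CatecholamineDoses:
    """Day-1 mean infusion rates, μg/kg/min."""

    dopamine: float = 0.0
    dobutamine: float = 0.0
    noradrenaline: float = 0.0
    adrenaline: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dopamine", "dobutamine", "noradrenaline", "adrenaline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} dose must be >= 0")

    @property
    def any_nonzero(self) -> bool:
        return any(
            getattr(self, n) > 0
            for n in ("dopamine", "dobutamine", "noradrenaline", "adrenaline")
        )


@dataclass(frozen=True)
class SofaBreakdown:
    respiratory: int
    cardiovascular: int
    coagulation: int
    liver: int
    renal: int
    cns: int

    def __post_init__(self) -> None:
        for name in ("respiratory", "cardiovascular", *LAB_COMPONENTS):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ValueError(f"SOFA component {name}={v} outside 0-4")

    @property
    def total(self) -> int:
        return (
            self.respiratory
            + self.cardiovascular
            + self.coagulation
            + self.liver
            + self.renal
            + self.cns
        )


def respiratory_sofa(support: OxygenSupport | str) -> int:
    """Respiratory component graded by support level: none 0 ... ECMO 4."""
    try:
        return _RESPIRATORY_SCORE[OxygenSupport(support)]
    except ValueError:
        raise ValueError(f"unknown oxygen support level: {support!r}") from None


def cardiovascular_sofa(
    doses: CatecholamineDoses, map_mmhg: float | None = None
) -> int:
    """Cardiovascular component from catecholamine doses.

    No catecholamines scores 0 whatever the mean arterial pressure (the
    claims-data modification); otherwise the standard SOFA dose bands apply:
    dopamine <=5 or any dobutamine -> 2; dopamine >5 or noradrenaline/
    adrenaline <=0.1 -> 3; dopamine >15 or noradrenaline/adrenaline >0.1 -> 4.
    """
    del map_mmhg  # intentionally ignored
    if not doses.any_nonzero:
        return 0
    score = 2  # any pressor/inotrope scores at least 2
    if doses.dopamine > 5 or 0 < doses.noradrenaline <= 0.1 or 0 < doses.adrenaline <= 0.1:
        score = 3
    if doses.dopamine > 15 or doses.noradrenaline > 0.1 or doses.adrenaline > 0.1:
        score = 4
    return score


def catecholamine_index(doses: CatecholamineDoses) -> float:
    """Dopamine + dobutamine + 100*noradrenaline + 100*adrenaline (μg/kg/min)."""
    return (
        doses.dopamine
        + doses.dobutamine
        + 100.0 * doses.noradrenaline
        + 100.0 * doses.adrenaline
    )


def total_sofa(record) -> SofaBreakdown:
    """Assemble the six-component breakdown for one patient record.

    ``record`` needs ``oxygen_support``, ``catecholamine_doses`` and a
    ``lab_subscores`` mapping with keys coagulation/liver/renal/cns.
    """
    subscores = {}
    for name in LAB_COMPONENTS:
        value = record.lab_subscores.get(name)
        if value is None:
            raise ValueError(f"missing SOFA subscore: {name}")
        subscores[name] = int(value)
    return SofaBreakdown(
        respiratory=respiratory_sofa(record.oxygen_support),
        cardiovascular=cardiovascular_sofa(record.catecholamine_doses),
        **subscores,
    )


def add_severity(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append ``sofa_total`` and ``catecholamine_index`` columns."""
    resp = cohort["oxygen_support"].map(
        {level.value: score for level, score in _RESPIRATORY_SCORE.items()}
    )
    if resp.isna().any():
        bad = cohort.loc[resp.isna(), "oxygen_support"].iloc[0]
        raise ValueError(f"unknown oxygen support level: {bad!r}")
    doa = cohort["dopamine"].to_numpy(float)
    dob = cohort["dobutamine"].to_numpy(float)
    na = cohort["noradrenaline"].to_numpy(float)
    ad = cohort["adrenaline"].to_numpy(float)
    if (doa < 0).any() or (dob < 0).any() or (na < 0).any() or (ad < 0).any():
        raise ValueError("catecholamine doses must be >= 0")
    any_dose = (doa > 0) | (dob > 0) | (na > 0) | (ad > 0)
    cv = np.where(any_dose, 2, 0)
    cv = np.where(
        (doa > 5) | ((na > 0) & (na <= 0.1)) | ((ad > 0) & (ad <= 0.1)), 3, cv
    )
    cv = np.where((doa > 15) | (na > 0.1) | (ad > 0.1), 4, cv)
    labs = cohort[[f"sofa_{c}" for c in LAB_COMPONENTS]].to_numpy(int)
    out = cohort.copy()
    out["sofa_total"] = resp.to_numpy(int) + cv + labs.sum(axis=1)
    out["catecholamine_index"] = doa + dob + 100.0 * na + 100.0 * ad
    return out
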