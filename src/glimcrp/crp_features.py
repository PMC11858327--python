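"""Early CRP trajectory features.

C-reactive protein (CRP, mg/dL) is an acute-phase marker that rises 4-6 h
after an insult and peaks around 36 h, so a single admission-day value can
miss the inflammatory burden of a newly admitted ICU patient.  The features
computed here summarise the first three hospital days (day 0 = admission):

* ``crp_day0``     — the day-0 level,
* ``crp_max_d01``  — the maximum over days 0-1,
* ``crp_max_d02``  — the maximum over days 0-2.

Because CRP is not drawn every day in routine care, missing values on days
0-2 are first filled by linear interpolation against the observed
measurements on days 0-6.  A missing day that precedes the first observation
(or follows the last) takes the nearest observed value — the flat boundary
case of linear interpolation.  Patients observed on *all* of days 0, 1 and 2
form the complete-case subset; everyone with at least one measurement in the
week belongs to the all-case population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Hospital days carried by a CRP series (day 0 = admission day).
DAYS = tuple(range(7))

#: Cohort-table column names for the daily CRP values.
CRP_COLUMNS = tuple(f"crp_day{d}" for d in DAYS)

#: Columns added by :func:`add_crp_features`.
FEATURE_COLUMNS = (
    "crp_day0",
    "crp_max_d01",
    "crp_max_d02",
    "complete_case",
    "imputed_day0",
    "imputed_day1",
    "imputed_day2",
)


@dataclass(frozen=True)
class CrpSeries:
    """Daily CRP values for hospital days 0-6.

    Parameters
    ----------
    values
        Length-7 float array, ``nan`` where no value is available.
    observed
        Length-7 boolean array flagging *measured* (as opposed to
        interpolated) days.  Defaults to ``~isnan(values)``; an interpolated
        series keeps the original flags, so imputed days are the non-observed
        days that now carry a value.
    """

    values: np.ndarray
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (7,):
            raise ValueError(f"CRP series must cover days 0-6, got shape {values.shape}")
        observed = self.observed
        if observed is None:
            observed = ~np.isnan(values)
        observed = np.asarray(observed, dtype=bool)
        if observed.shape != (7,):
            raise ValueError("observed flags must cover days 0-6")
        if np.isnan(values[observed]).any():
            raise ValueError("observed days must carry a value")
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("CRP values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed", observed)

    @classmethod
    def from_mapping(cls, day_to_value: dict[int, float]) -> "CrpSeries":
        """Build a series from ``{day: mg/dL}``; unlisted days are missing."""
        values = np.full(7, np.nan)
        for day, value in day_to_value.items():
            if day not in DAYS:
                raise ValueError(f"day {day} outside 0-6")
            values[day] = value
        return cls(values)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def imputed_days(self) -> tuple[int, ...]:
        """Days 0-2 carrying a value that was not measured."""
        filled = ~np.isnan(self.values[:3]) & ~self.observed[:3]
        return tuple(int(d) for d in np.flatnonzero(filled))


@dataclass(frozen=True)
class CrpFeatures:
    """Windowed CRP statistics for one patient."""

    crp_day0: float
    crp_max_d01: float
    crp_max_d02: float
    complete_case: bool
    imputed_days: tuple[int, ...] = ()


def interpolate_crp(series: CrpSeries) -> CrpSeries:
    """Fill missing CRP on days 0-2 from the observed days 0-6.

    Each missing day in ``{0, 1, 2}`` with observed neighbours on both sides
    receives the linear interpolant between the nearest observed days; a
    missing day outside the observed range takes the nearest observed value.
    Observed values are never altered, and days 3-6 are left as they are.

    Raises
    ------
    ValueError
        If the series has no observed value at all (such patients are
        excluded upstream by the eligibility rules).
    """
    obs_days = np.flatnonzero(series.observed)
    if obs_days.size == 0:
        raise ValueError("cannot interpolate a CRP series with no observed values")
    values = series.values.copy()
    missing_early = [d for d in (0, 1, 2) if not series.observed[d]]
    if missing_early:
        # np.interp is linear inside the observed range and clamps (flat
        # carry) outside it, which is exactly the boundary rule used here.
        values[missing_early] = np.interp(
            missing_early, obs_days, series.values[obs_days]
        )
    return CrpSeries(values=values, observed=series.observed.copy())


def crp_features(filled: CrpSeries, original: CrpSeries | None = None) -> CrpFeatures:
    """Compute the three windowed statistics from an interpolated series.

    ``original`` supplies the measurement flags for the complete-case
    decision; it defaults to ``filled`` itself, whose ``observed`` flags are
    preserved by :func:`interpolate_crp`.
    """
    if np.isnan(filled.values[:3]).any():
        raise ValueError("days 0-2 must be filled before computing features")
    source = filled if original is None else original
    complete = bool(source.observed[:3].all())
    return CrpFeatures(
        crp_day0=float(filled.values[0]),
        crp_max_d01=float(filled.values[:2].max()),
        crp_max_d02=float(filled.values[:3].max()),
        complete_case=complete,
        imputed_days=filled.imputed_days,
    )


def add_crp_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the CRP feature columns to a cohort table.

    Vectorised equivalent of running :func:`interpolate_crp` and
    :func:`crp_features` on every row; rows without any observed CRP raise,
    matching the scalar path.
    """
    crp = cohort.loc[:, list(CRP_COLUMNS)].astype(float)
    if crp.isna().all(axis=1).any():
        raise ValueError("cohort contains rows with no observed CRP on days 0-6")
    observed = crp.notna()
    # Linear interpolation along the day axis, then flat carry at both ends.
    filled = (
        crp.interpolate(axis=1, method="linear", limit_direction="forward")
        .ffill(axis=1)
        .bfill(axis=1)
    )
    out = cohort.copy()
    out["crp_day0"] = filled["crp_day0"]
    out["crp_max_d01"] = filled[["crp_day0", "crp_day1"]].max(axis=1)
    out["crp_max_d02"] = filled[["crp_day0", "crp_day1", "crp_day2"]].max(axis=1)
    out["complete_case"] = observed[["crp_day0", "crp_day1", "crp_day2"]].all(axis=1)
    for d in (0, 1, 2):
        out[f"imputed_day{d}"] = ~observed[f"crp_day{d}"]
    return out
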