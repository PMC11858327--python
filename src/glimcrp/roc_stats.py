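"""ROC curves, AUC and Youden-index cut-off discovery.

The discriminative value of each windowed CRP statistic for the composite
outcome is summarised by a ROC curve swept over the observed score values
(a score counts as predicted-positive when it is >= the threshold), its
trapezoidal AUC — which for this construction equals the Mann-Whitney
pair-counting probability with ties counted 1/2 — and the cut-off maximising
the Youden index J = sensitivity + specificity - 1.  The sweep is repeated
per analysis population (all-case / complete-case), per CRP window (day 0,
days 0-1, days 0-2) and per diagnosis subgroup, mirroring a stratified
cut-off table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_builder import DiagnosisCategory

WINDOWS = {"day0": "crp_day0", "d01": "crp_max_d01", "d02": "crp_max_d02"}
POPULATIONS = ("all_case", "complete_case")
SUBGROUPS = ("all",) + tuple(c.value for c in DiagnosisCategory)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep over observed score values.

    ``thresholds`` is descending and starts with an ``inf`` sentinel at which
    nothing is called positive, so the curve starts at (sens, 1-spec) = (0, 0)
    and ends at (1, 1) once every observation is called positive.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffReport:
    """One row of a stratified AUC / optimal cut-off table."""

    auc: float
    optimal_cutoff: float | None
    youden_j: float | None
    sens_at_cutoff: float | None
    spec_at_cutoff: float | None
    subgroup: str = "all"
    window: str = "d02"
    population: str = "all_case"
    n_pos: int = 0
    n_neg: int = 0
    undefined: bool = False


def build_roc(scores, labels) -> ROCCurve:
    """Sweep sensitivity/specificity over the distinct observed scores.

    Tied scores enter and leave the positive call together, which makes the
    trapezoidal AUC of this curve identical to the rank statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-d sequences")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate outcome: need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each run of tied scores -> cumulative TP/FP with ties grouped
    last_of_run = np.flatnonzero(np.diff(s) != 0)
    boundaries = np.append(last_of_run, s.size - 1)
    tp = np.cumsum(y)[boundaries]
    fp = np.cumsum(~y)[boundaries]
    thresholds = np.concatenate(([np.inf], s[boundaries]))
    sensitivity = np.concatenate(([0.0], tp / n_pos))
    specificity = np.concatenate(([1.0], 1.0 - fp / n_neg))
    return ROCCurve(thresholds, sensitivity, specificity, n_pos, n_neg)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under (1-specificity, sensitivity)."""
    x = 1.0 - curve.specificity
    return float(np.trapezoid(curve.sensitivity, x))


def youden_optimal(curve: ROCCurve) -> CutoffReport:
    """Cut-off maximising J = sens + spec - 1 over observed score values.

    Ties in J are broken toward the smallest cut-off (favouring sensitivity
    in a screening setting); the sentinel threshold is never selected.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    j_obs = j[1:]  # skip the sentinel
    best_j = j_obs.max()
    # J values built from different sens/spec pairs can differ by one ulp
    # even when mathematically tied, so ties are detected with a tolerance;
    # thresholds are descending, so the last tied index is the smallest value.
    best_idx = int(np.flatnonzero(j_obs >= best_j - 1e-12)[-1]) + 1
    return CutoffReport(
        auc=auc(curve),
        optimal_cutoff=float(curve.thresholds[best_idx]),
        youden_j=float(j[best_idx]),
        sens_at_cutoff=float(curve.sensitivity[best_idx]),
        spec_at_cutoff=float(curve.specificity[best_idx]),
        n_pos=curve.n_pos,
        n_neg=curve.n_neg,
    )


def sens_spec_at(scores, labels, cutoff: float, strict: bool = False) -> tuple[float, float]:
    """Sensitivity and specificity at a fixed external cut-off.

    ``strict`` selects score > cutoff as the positive call; otherwise
    score >= cutoff (the ROC sweep convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate outcome: need at least one positive and one negative")
    called = scores > cutoff if strict else scores >= cutoff
    sens = float((called & labels).sum() / n_pos)
    spec = float((~called & ~labels).sum() / n_neg)
    return sens, spec


def _undefined_reports(population: str, subgroup: str, n_pos: int, n_neg: int):
    return [
        CutoffReport(
            auc=float("nan"),
            optimal_cutoff=None,
            youden_j=None,
            sens_at_cutoff=None,
            spec_at_cutoff=None,
            subgroup=subgroup,
            window=window,
            population=population,
            n_pos=n_pos,
            n_neg=n_neg,
            undefined=True,
        )
        for window in WINDOWS
    ]


def windowed_subgroup_analysis(cohort: pd.DataFrame) -> list[CutoffReport]:
    """AUC for every population x window x subgroup cell, 54 reports in all.

    Within each (population, subgroup) row the Youden cut-off is reported
    only for the window with the highest AUC (ties broken toward the wider
    window); the other windows carry the AUC alone.  A stratum with a single
    outcome class yields reports flagged ``undefined`` rather than an error.
    """
    reports: list[CutoffReport] = []
    for population in POPULATIONS:
        pop_df = cohort if population == "all_case" else cohort.loc[cohort["complete_case"]]
        for subgroup in SUBGROUPS:
            sub = pop_df if subgroup == "all" else pop_df.loc[pop_df["diagnosis_category"] == subgroup]
            labels = sub["composite"].to_numpy(bool) if len(sub) else np.array([], bool)
            n_pos, n_neg = int(labels.sum()), int((~labels).sum())
            if n_pos == 0 or n_neg == 0:
                reports.extend(_undefined_reports(population, subgroup, n_pos, n_neg))
                continue
            curves = {
                window: build_roc(sub[column].to_numpy(float), labels)
                for window, column in WINDOWS.items()
            }
            aucs = {window: auc(curve) for window, curve in curves.items()}
            # ties toward the wider window, the last in WINDOWS order
            best_window = max(WINDOWS, key=lambda w: (aucs[w], list(WINDOWS).index(w)))
            for window, curve in curves.items():
                if window == best_window:
                    report = replace(
                        youden_optimal(curve),
                        subgroup=subgroup,
                        window=window,
                        population=population,
                    )
                else:
                    report = CutoffReport(
                        auc=aucs[window],
                        optimal_cutoff=None,
                        youden_j=None,
                        sens_at_cutoff=None,
                        spec_at_cutoff=None,
                        subgroup=subgroup,
                        window=window,
                        population=population,
                        n_pos=curve.n_pos,
                        n_neg=curve.n_neg,
                    )
                reports.append(report)
    return reports


def reports_to_table(reports: list[CutoffReport]) -> pd.DataFrame:
    """Pivot the 54 reports into an 18-row stratified AUC table.

    One row per population x subgroup with the three window AUCs and the
    optimal cut-off from the best window.
    """
    rows = []
    for population in POPULATIONS:
        for subgroup in SUBGROUPS:
            cell = [
                r for r in reports
                if r.population == population and r.subgroup == subgroup
            ]
            if not cell:
                continue
            by_window = {r.window: r for r in cell}
            best = next((r for r in cell if r.optimal_cutoff is not None), None)
            rows.append(
                {
                    "population": population,
                    "subgroup": subgroup,
                    "auc_day0": by_window["day0"].auc,
                    "auc_d01": by_window["d01"].auc,
                    "auc_d02": by_window["d02"].auc,
                    "best_window": best.window if best else None,
                    "optimal_cutoff": best.optimal_cutoff if best else None,
                    "youden_j": best.youden_j if best else None,
                    "sens_at_cutoff": best.sens_at_cutoff if best else None,
                    "spec_at_cutoff": best.spec_at_cutoff if best else None,
                    "undefined": all(r.undefined for r in cell),
                }
            )
    return pd.DataFrame(rows)


def roc_points(cohort: pd.DataFrame, window: str = "d02") -> pd.DataFrame:
    """ROC point dump (threshold, sensitivity, 1-specificity) for plotting."""
    curve = build_roc(
        cohort[WINDOWS[window]].to_numpy(float), cohort["composite"].to_numpy(bool)
    )
    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "one_minus_specificity": 1.0 - curve.specificity,
        }
    )
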