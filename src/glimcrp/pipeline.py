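"""End-to-end analysis pipeline and report surfaces.

``run_pipeline`` takes a cohort CSV (or a generator spec), applies the
eligibility rules, categorises diagnoses, computes severity scores and CRP
features, derives outcomes, discovers (or accepts) the CRP cut-off, labels
the four GLIM groups, and writes the report tables:

* ``attrition.csv``        — flowchart counts per exclusion reason
* ``cohort_included.csv``  — the analysed cohort with all derived columns
* ``table1_auc.csv``       — stratified window AUCs and optimal cut-offs
* ``table2_characteristics.csv`` — per-group clinical characteristics
* ``table3_outcomes.csv``  — per-group outcome summaries with KW results
* ``pvalues.csv``          — long-format raw/adjusted Conover p-values
* ``roc_points.csv``       — ROC point dump for the days 0-2 window
* ``run_metadata.json``    — config echo, version and row counts

Outputs are deterministic for a fixed config and input.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort_builder import (
    add_diagnosis_category,
    attrition_table,
    filter_included,
)
from .crp_features import add_crp_features
from .group_compare import compare_four_groups, comparisons_to_tables
from .outcomes_glim import GROUP_ORDER, add_four_group, add_outcomes, four_group_summary, percent
from .roc_stats import reports_to_table, roc_points, windowed_subgroup_analysis
from .severity import add_severity
from .synthetic_cohort import CohortSpec, generate_cohort, read_cohort_csv, write_cohort_csv

logger = logging.getLogger("glimcrp")


class RunConfig(BaseModel):
    """Configuration for one analysis run."""

    input_csv: Union[str, None] = None
    spec: Union[CohortSpec, None] = None
    population: Literal["all_case", "complete_case", "both"] = "both"
    crp_cutoff: Union[Literal["youden"], float] = "youden"
    alpha: float = Field(gt=0, lt=1, default=0.05)
    seed: Union[int, None] = None
    outdir: str = "glimcrp_run"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.input_csv is None) == (self.spec is None):
            raise ValueError("exactly one of input_csv or spec must be given")
        if isinstance(self.crp_cutoff, float) and self.crp_cutoff <= 0:
            raise ValueError("crp_cutoff must be positive when fixed")
        return self


_CHARACTERISTIC_BINARIES = ("chdf", "ihd", "iabp", "low_bmi")


def _table2(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group clinical characteristics (age, sex, BMI, severity, mix)."""
    frames = [("overall", cohort)] + [
        (g.value, cohort.loc[cohort["four_group"] == g.value]) for g in GROUP_ORDER
    ]
    rows = []
    for name, sub in frames:
        n = len(sub)
        row: dict[str, object] = {"group": name, "n": n}
        if n == 0:
            rows.append(row)
            continue
        row["age_mean"] = round(float(sub["age"].mean()), 1)
        row["age_sd"] = round(float(sub["age"].std()), 1)
        row["male_n"] = int((sub["sex"] == "male").sum())
        row["male_pct"] = percent(row["male_n"], n)
        row["bmi_mean"] = round(float(sub["bmi"].mean()), 1)
        row["bmi_sd"] = round(float(sub["bmi"].std()), 1)
        row["sofa_mean"] = round(float(sub["sofa_total"].mean()), 1)
        row["sofa_sd"] = round(float(sub["sofa_total"].std()), 1)
        row["catecholamine_index_mean"] = round(float(sub["catecholamine_index"].mean()), 1)
        mv = int((sub["oxygen_support"] == "mechanical_ventilation").sum())
        ecmo = int((sub["oxygen_support"] == "ecmo").sum())
        row["mechanical_ventilation_n"] = mv
        row["mechanical_ventilation_pct"] = percent(mv, n)
        row["ecmo_n"] = ecmo
        row["ecmo_pct"] = percent(ecmo, n)
        for col in _CHARACTERISTIC_BINARIES:
            count = int(sub[col].sum())
            row[f"{col}_n"] = count
            row[f"{col}_pct"] = percent(count, n)
        row["crp_day0_mean"] = round(float(sub["crp_day0"].mean()), 1)
        row["crp_max_d02_mean"] = round(float(sub["crp_max_d02"].mean()), 1)
        for cat in sorted(cohort["diagnosis_category"].unique()):
            count = int((sub["diagnosis_category"] == cat).sum())
            row[f"dx_{cat}_n"] = count
            row[f"dx_{cat}_pct"] = percent(count, n)
        rows.append(row)
    return pd.DataFrame(rows)


def prepare_cohort(raw: pd.DataFrame) -> pd.DataFrame:
    """Screen, categorise and featurise a raw cohort table."""
    logger.info("screened %d admissions", len(raw))
    included = filter_included(raw)
    logger.info("included %d admissions", len(included))
    if included.empty:
        raise ValueError("no admissions pass the eligibility rules")
    included = add_diagnosis_category(included)
    included = add_severity(included)
    included = add_crp_features(included)
    included = add_outcomes(included)
    return included


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full analysis and write every report under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.spec is not None:
        spec = config.spec
        if config.seed is not None:
            spec = spec.model_copy(update={"seed": config.seed})
        raw = generate_cohort(spec)
        write_cohort_csv(raw, outdir / "cohort_raw.csv")
    else:
        raw = read_cohort_csv(config.input_csv)

    attrition = attrition_table(raw)
    cohort = prepare_cohort(raw)

    analysis = cohort if config.population != "complete_case" else cohort.loc[cohort["complete_case"]].reset_index(drop=True)
    reports = windowed_subgroup_analysis(cohort)
    table1 = reports_to_table(reports)
    if config.population != "both":
        table1 = table1.loc[table1["population"] == config.population].reset_index(drop=True)

    if config.crp_cutoff == "youden":
        # cut-off from the all-case, all-diagnoses, days 0-2 window
        headline = next(
            r for r in reports
            if r.population == "all_case" and r.subgroup == "all" and r.window == "d02"
        )
        if headline.optimal_cutoff is None:
            headline = next(
                r for r in reports
                if r.population == "all_case" and r.subgroup == "all"
                and r.optimal_cutoff is not None
            )
        cutoff = float(headline.optimal_cutoff)
    else:
        cutoff = float(config.crp_cutoff)
    logger.info("CRP cut-off: %.2f mg/dL", cutoff)

    analysis = add_four_group(analysis, cutoff)
    comparisons = compare_four_groups(analysis)
    table3_outcomes, pvalues = comparisons_to_tables(comparisons)
    table3_groups = four_group_summary(analysis)
    table2 = _table2(analysis)

    attrition.to_csv(outdir / "attrition.csv", index=False)
    analysis.to_csv(outdir / "cohort_included.csv", index=False)
    table1.to_csv(outdir / "table1_auc.csv", index=False)
    table2.to_csv(outdir / "table2_characteristics.csv", index=False)
    table3_groups.to_csv(outdir / "table3_outcomes.csv", index=False)
    table3_outcomes.to_csv(outdir / "table3_tests.csv", index=False)
    pvalues.to_csv(outdir / "pvalues.csv", index=False)
    roc_points(cohort, "d02").to_csv(outdir / "roc_points.csv", index=False)

    metadata = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "crp_cutoff_used": cutoff,
        "rows": {
            "screened": int(attrition.loc[attrition["stage"] == "screened", "count"].iloc[0]),
            "included": len(cohort),
            "analysed": len(analysis),
            "complete_case": int(cohort["complete_case"].sum()),
        },
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)

    return {
        "attrition": attrition,
        "cohort": cohort,
        "analysis": analysis,
        "reports": reports,
        "table1": table1,
        "table2": table2,
        "table3": table3_groups,
        "comparisons": comparisons,
        "pvalues": pvalues,
        "cutoff": cutoff,
        "outdir": outdir,
    }
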