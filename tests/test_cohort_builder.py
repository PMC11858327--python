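"""Eligibility screening and ICD-10 diagnosis categorisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glimcrp import (
    CrpSeries,
    DiagnosisCategory,
    apply_eligibility,
    attrition_table,
    categorize_diagnosis,
    filter_included,
    generate_cohort,
)
from glimcrp.cohort_builder import EXCLUSION_REASONS, eligibility_frame
from glimcrp.severity import CatecholamineDoses
from glimcrp.synthetic_cohort import PatientRecord

from conftest import make_spec


def make_record(**overrides) -> PatientRecord:
    base = dict(
        patient_id="P0",
        age=65.0,
        sex="male",
        bmi=22.0,
        icd10_codes=["I63.9"],
        has_sepsis_code=False,
        emergent_admission=True,
        icu_consecutive_days=4,
        hospital_los_days=12,
        died_in_hospital=False,
        death_day=None,
        barthel_index=80,
        crp=CrpSeries.from_mapping({0: 2.0, 2: 5.0}),
        oxygen_support="oxygen",
        chdf=False,
        ihd=False,
        iabp=False,
        catecholamine_doses=CatecholamineDoses(),
        lab_subscores={"coagulation": 0, "liver": 0, "renal": 0, "cns": 0},
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestEligibility:
    def test_fully_eligible_record_is_included(self):
        result = apply_eligibility(make_record())
        assert result.included and result.exclusion_reasons == ()

    def test_minor_is_excluded_for_age(self):
        result = apply_eligibility(make_record(age=17.0))
        assert result.exclusion_reasons == ("age_lt_18",)

    def test_short_icu_and_short_stay_both_reported(self):
        result = apply_eligibility(
            make_record(icu_consecutive_days=2, hospital_los_days=4)
        )
        assert result.exclusion_reasons == ("icu_days_lt_3", "hospital_los_lt_5")

    def test_missing_fields_become_reasons_not_errors(self):
        record = make_record(age=None, bmi=None, barthel_index=None)
        result = apply_eligibility(record)
        assert result.exclusion_reasons == ("missing_bi", "missing_bmi", "missing_age")

    def test_no_crp_reason(self):
        record = make_record(crp=CrpSeries(np.full(7, np.nan)))
        assert apply_eligibility(record).exclusion_reasons == ("no_crp_within_7_days",)

    def test_reasons_follow_fixed_order(self):
        record = make_record(
            age=16.0, emergent_admission=False, icu_consecutive_days=1,
            hospital_los_days=2, barthel_index=None, bmi=None,
            crp=CrpSeries(np.full(7, np.nan)),
        )
        reasons = apply_eligibility(record).exclusion_reasons
        assert list(reasons) == [r for r in EXCLUSION_REASONS if r in reasons]
        # every violated rule is reported: age, emergency, ICU days, LOS,
        # missing BI, missing BMI, no CRP
        assert len(reasons) == 7

    def test_boundary_values_are_included(self):
        record = make_record(age=18.0, icu_consecutive_days=3, hospital_los_days=5)
        assert apply_eligibility(record).included


class TestFrameScreening:
    def test_flowchart_identity(self):
        cohort = generate_cohort(make_spec(n_patients=1500, seed=4))
        table = attrition_table(cohort).set_index("stage")["count"]
        assert table["included"] + table["excluded"] == len(cohort)
        assert len(filter_included(cohort)) == table["included"]

    def test_frame_agrees_with_scalar_screening(self):
        cohort = generate_cohort(make_spec(n_patients=400, seed=6))
        flags = eligibility_frame(cohort)
        for idx in range(0, 400, 7):
            record = PatientRecord.from_row(cohort.iloc[idx])
            assert apply_eligibility(record).included == bool(flags["included"].iloc[idx])


class TestCategorisation:
    @pytest.mark.parametrize(
        "codes,sepsis,expected",
        [
            (["I63"], False, DiagnosisCategory.NEUROLOGY),
            (["I21"], True, DiagnosisCategory.SEPSIS),
            (["Z99"], False, DiagnosisCategory.OTHERS),
            (["I21.9"], False, DiagnosisCategory.CARDIOVASCULAR),
            (["G41.0"], False, DiagnosisCategory.NEUROLOGY),
            (["J18"], False, DiagnosisCategory.PULMONARY),
            (["E11.1"], False, DiagnosisCategory.METABOLIC),
            (["S06"], False, DiagnosisCategory.TRAUMA),
            (["T07"], False, DiagnosisCategory.TRAUMA),
            (["T20"], False, DiagnosisCategory.OTHERS),
            (["T33"], False, DiagnosisCategory.TRAUMA),
            (["V89.2"], False, DiagnosisCategory.TRAUMA),
            (["Y09"], False, DiagnosisCategory.TRAUMA),
            (["Y10"], False, DiagnosisCategory.OTHERS),
            (["K65"], False, DiagnosisCategory.DIGESTIVE),
            (["K10"], False, DiagnosisCategory.OTHERS),
            ([], False, DiagnosisCategory.OTHERS),
        ],
    )
    def test_code_ranges(self, codes, sepsis, expected):
        assert categorize_diagnosis(codes, sepsis) == expected

    def test_first_code_decides_among_non_sepsis_codes(self):
        assert categorize_diagnosis(["J18", "I21"], False) == DiagnosisCategory.PULMONARY
        assert categorize_diagnosis(["I21", "J18"], False) == DiagnosisCategory.CARDIOVASCULAR

    def test_malformed_code_raises_naming_the_code(self):
        with pytest.raises(ValueError, match="i63"):
            categorize_diagnosis(["i63"], False)

    @given(
        codes=st.lists(
            st.from_regex(r"[A-Z][0-9]{2}", fullmatch=True), min_size=1, max_size=4
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_sepsis_flag_always_wins(self, codes):
        assert categorize_diagnosis(codes, True) == DiagnosisCategory.SEPSIS

    @given(codes=st.lists(st.from_regex(r"[A-Z][0-9]{2}", fullmatch=True), min_size=1, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_every_code_set_gets_exactly_one_category(self, codes):
        category = categorize_diagnosis(codes, False)
        assert isinstance(category, DiagnosisCategory)

    def test_generator_code_pools_round_trip(self):
        from glimcrp.synthetic_cohort import _CODE_POOLS

        for category, pool in _CODE_POOLS.items():
            for code in pool:
                got = categorize_diagnosis([code], category == "sepsis")
                assert got.value == category, (code, got)

    def test_labelled_cohort_partitions(self):
        from glimcrp.cohort_builder import add_diagnosis_category

        cohort = generate_cohort(make_spec(n_patients=2000, seed=12))
        labelled = add_diagnosis_category(cohort)
        assert (
            labelled.loc[labelled["has_sepsis_code"], "diagnosis_category"] == "sepsis"
        ).all()
        assert labelled["diagnosis_category"].value_counts().sum() == len(cohort)
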