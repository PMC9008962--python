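"""Shared fixtures: record factories and a hand-scored 10-admission cohort."""

from __future__ import annotations

import numpy as np
import pytest

from ugibrisk.patient_model import (
    CohortRow,
    OutcomeLabels,
    PatientRecord,
    make_row,
)

#: An unremarkable younger admission: scores 0 on every additive system and
#: the healthiest possible T-score (12).
NORMAL_KWARGS = dict(
    age=40,
    sex="male",
    systolic_bp=120.0,
    pulse=70.0,
    hemoglobin=14.0,
    urea=5.0,
    creatinine=80.0,
    albumin=40.0,
    inr=1.0,
    gcs=15,
    asa=1,
    general_condition="good",
    melena=False,
    syncope=False,
    liver_disease=False,
    cirrhosis=False,
    heart_failure=False,
    ischemic_heart_disease=False,
    renal_failure=False,
    liver_failure=False,
    metastatic_or_disseminated_malignancy=False,
    other_major_comorbidity=False,
)

#: Every risk marker at its worst: each additive system attains its printed
#: maximum, the T-score its minimum (4).
WORST_KWARGS = dict(
    NORMAL_KWARGS,
    age=85,
    sex="female",
    systolic_bp=70.0,
    pulse=130.0,
    hemoglobin=5.0,
    urea=30.0,
    creatinine=200.0,
    albumin=15.0,
    inr=3.0,
    gcs=3,
    asa=5,
    general_condition="poor",
    melena=True,
    syncope=True,
    liver_disease=True,
    cirrhosis=True,
    heart_failure=True,
    ischemic_heart_disease=True,
    renal_failure=True,
    liver_failure=True,
    metastatic_or_disseminated_malignancy=True,
    other_major_comorbidity=True,
)


def make_record(**overrides) -> PatientRecord:
    return PatientRecord(**{**NORMAL_KWARGS, **overrides})


def make_cohort_row(record: PatientRecord, **outcome_overrides) -> CohortRow:
    outcomes = dict(death_30d=False, intervention=False, rebleeding=False,
                    icu_admission=False)
    outcomes.update(outcome_overrides)
    return make_row(record, OutcomeLabels(**outcomes))


# Ten admissions with all six totals worked out by hand from the published
# rubrics.  Expected order: (ABC, AIMS65, GBS, MAPASH, PRS, TSCORE).
HAND_SCORED = [
    (make_record(), (0, 0, 0, 0, 0, 12)),
    (make_record(age=55, sex="female"), (0, 0, 0, 0, 0, 12)),
    (make_record(albumin=25.0, inr=1.8, systolic_bp=85.0, age=70),
     (3, 4, 3, 2, 3, 10)),
    (make_record(urea=12.0, hemoglobin=9.5, systolic_bp=95.0, pulse=105.0,
                 melena=True, liver_disease=True),
     (1, 0, 16, 3, 2, 9)),
    (make_record(age=82, systolic_bp=88.0,
                 metastatic_or_disseminated_malignancy=True),
     (6, 2, 3, 2, 7, 10)),
    (make_record(age=70, pulse=110.0, ischemic_heart_disease=True),
     (1, 1, 1, 1, 4, 11)),
    (make_record(general_condition="intermediate", pulse=95.0,
                 systolic_bp=100.0, hemoglobin=9.5),
     (0, 0, 7, 2, 0, 8)),
    (make_record(gcs=14, albumin=24.0, asa=3, systolic_bp=85.0, pulse=110.0,
                 hemoglobin=9.0),
     (5, 2, 10, 9, 2, 8)),
    (make_record(age=65, urea=8.0, albumin=35.0, creatinine=120.0, asa=3),
     (3, 0, 3, 1, 1, 12)),
    (PatientRecord(**WORST_KWARGS), (18, 5, 23, 9, 7, 4)),
]


@pytest.fixture
def hand_scored():
    return HAND_SCORED


@pytest.fixture
def rng():
    return np.random.default_rng(20220413)
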