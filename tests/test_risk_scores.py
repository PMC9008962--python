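"""The six scoring rubrics: worked examples, ranges, monotonicity."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugibrisk.patient_model import PatientRecord
from ugibrisk.risk_scores import (
    SYSTEM_ORDER,
    SYSTEMS,
    enumerate_rubric,
    score_abc,
    score_aims65,
    score_all,
    score_gbs,
    score_mapash,
    score_prs,
    score_tscore,
)

from conftest import NORMAL_KWARGS, make_record


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(albumin=25.0, inr=1.8, gcs=15, systolic_bp=85.0, age=70), 4),
        (dict(), 0),
        (dict(age=66), 1),          # age strictly > 65 scores
        (dict(age=65), 0),
        (dict(gcs=14), 0),          # altered mental status here is GCS < 14
        (dict(gcs=13), 1),
        (dict(inr=1.5), 0),         # strict inequality
    ],
)
def test_aims65_examples(overrides, expected):
    assert score_aims65(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(urea=12.0, hemoglobin=9.5, systolic_bp=95.0, pulse=105.0,
              melena=True, liver_disease=True), 16),
        (dict(sex="female", hemoglobin=13.0, urea=5.0, systolic_bp=130.0), 0),
        # band boundaries (half-open intervals)
        (dict(urea=6.5), 2),
        (dict(urea=8.0), 3),
        (dict(urea=10.0), 4),
        (dict(urea=25.0), 6),
        (dict(hemoglobin=12.0), 1),        # man, 12 <= Hb < 13
        (dict(hemoglobin=12.0, sex="female"), 0),
        (dict(hemoglobin=11.0, sex="female"), 1),
        (dict(systolic_bp=109.0), 1),
        (dict(systolic_bp=110.0), 0),
        (dict(pulse=100.0), 1),            # GBS pulse criterion is >= 100
        (dict(pulse=99.9), 0),
    ],
)
def test_gbs_examples(overrides, expected):
    assert score_gbs(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(age=82, systolic_bp=88.0,
              metastatic_or_disseminated_malignancy=True), 7),
        (dict(age=45, systolic_bp=130.0, pulse=80.0), 0),
        (dict(age=70, systolic_bp=120.0, pulse=110.0,
              ischemic_heart_disease=True), 4),
        (dict(age=80), 2),                  # >=80 band so age 80 is scored
        (dict(age=60), 1),
        # hypotension dominates tachycardia; pulse 101 with SBP 99 scores 2
        (dict(systolic_bp=99.0, pulse=101.0), 2),
        (dict(systolic_bp=100.0, pulse=101.0), 1),
        (dict(pulse=100.0), 0),             # pRS shock pulse criterion is > 100
        # highest comorbidity tier applies, tiers never add
        (dict(renal_failure=True, heart_failure=True), 3),
    ],
)
def test_prs_examples(overrides, expected):
    assert score_prs(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(general_condition="good", pulse=80.0, systolic_bp=130.0,
              hemoglobin=12.0), 12),
        (dict(general_condition="poor", pulse=120.0, systolic_bp=85.0,
              hemoglobin=8.0), 4),
        (dict(general_condition="intermediate", pulse=95.0,
              systolic_bp=100.0, hemoglobin=9.5), 8),
        # closed middle bands: boundary values grade 2
        (dict(pulse=90.0, systolic_bp=110.0, hemoglobin=9.0), 3 + 2 + 2 + 2),
        (dict(pulse=110.0, systolic_bp=90.0, hemoglobin=10.0), 3 + 2 + 2 + 2),
    ],
)
def test_tscore_examples(overrides, expected):
    assert score_tscore(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(gcs=14, albumin=24.0, asa=3, systolic_bp=85.0, pulse=110.0,
              hemoglobin=9.0), 9),
        (dict(), 0),
        (dict(gcs=15, albumin=30.0, asa=4, systolic_bp=95.0, pulse=105.0,
              hemoglobin=11.0), 2),
        (dict(albumin=25.0), 0),            # strict < 2.5 g/dL
        (dict(albumin=24.9), 2),
        (dict(gcs=14), 1),                  # altered mental status is GCS < 15
    ],
)
def test_mapash_examples(overrides, expected):
    assert score_mapash(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(age=78, urea=11.0, albumin=28.0, creatinine=160.0, gcs=14,
              cirrhosis=True, liver_disease=True,
              metastatic_or_disseminated_malignancy=True, asa=4), 18),
        (dict(), 0),
        (dict(age=65, urea=8.0, albumin=35.0, creatinine=120.0, asa=3), 3),
        (dict(creatinine=100.0), 1),        # closed band [100, 150]
        (dict(creatinine=150.0), 1),
        (dict(creatinine=150.1), 2),
        (dict(creatinine=99.9), 0),
        (dict(age=60), 1),
        (dict(age=75), 2),
    ],
)
def test_abc_examples(overrides, expected):
    assert score_abc(make_record(**overrides)).total == expected


def test_enumerate_rubric_matches_published_ranges():
    published = {"ABC": (0, 18), "AIMS65": (0, 5), "GBS": (0, 23),
                 "MAPASH": (0, 9), "PRS": (0, 7), "TSCORE": (4, 12)}
    for system, (lo, hi) in published.items():
        totals = enumerate_rubric(system)
        assert min(totals) == lo == SYSTEMS[system].min_total
        assert max(totals) == hi == SYSTEMS[system].max_total


def test_tscore_attains_every_integer_total():
    assert enumerate_rubric("TSCORE") == set(range(4, 13))


def test_enumerate_rubric_unknown_system():
    with pytest.raises(ValueError):
        enumerate_rubric("ROCKALL")


def test_score_all_hand_scored_cohort(hand_scored):
    for record, expected in hand_scored:
        results = score_all(record)
        got = tuple(results[s].total for s in SYSTEM_ORDER)
        assert got == expected, f"record {record} -> {got}, expected {expected}"
        for res in results.values():
            assert res.total == sum(res.components.values())


def test_scored_totals_stay_inside_enumerated_sets(hand_scored):
    attainable = {s: enumerate_rubric(s) for s in SYSTEM_ORDER}
    for record, _ in hand_scored:
        for system, res in score_all(record).items():
            assert res.total in attainable[system]


def test_determinism(hand_scored):
    record, _ = hand_scored[3]
    assert score_all(record) == score_all(record)


# ---------------------------------------------------------------------------
# property-based fuzzing


@st.composite
def records(draw):
    cirrhosis = draw(st.booleans())
    return make_record(
        age=draw(st.integers(18, 100)),
        sex=draw(st.sampled_from(["male", "female"])),
        systolic_bp=draw(st.floats(40, 260)),
        pulse=draw(st.floats(20, 250)),
        hemoglobin=draw(st.floats(2, 22)),
        urea=draw(st.floats(0.5, 100)),
        creatinine=draw(st.floats(10, 2500)),
        albumin=draw(st.floats(10, 60)),
        inr=draw(st.floats(0.5, 20)),
        gcs=draw(st.integers(3, 15)),
        asa=draw(st.integers(1, 5)),
        general_condition=draw(st.sampled_from(["poor", "intermediate", "good"])),
        melena=draw(st.booleans()),
        syncope=draw(st.booleans()),
        liver_disease=cirrhosis or draw(st.booleans()),
        cirrhosis=cirrhosis,
        heart_failure=draw(st.booleans()),
        ischemic_heart_disease=draw(st.booleans()),
        renal_failure=draw(st.booleans()),
        liver_failure=draw(st.booleans()),
        metastatic_or_disseminated_malignancy=draw(st.booleans()),
        other_major_comorbidity=draw(st.booleans()),
    )


@given(records())
@settings(max_examples=300, derandomize=True, deadline=None)
def test_totals_within_range_and_conserved(rec: PatientRecord):
    for system, res in score_all(rec).items():
        spec = SYSTEMS[system]
        assert spec.min_total <= res.total <= spec.max_total
        assert res.total == sum(res.components.values())
        assert isinstance(res.total, int)


#: Single-component worsenings: each transform makes exactly one risk factor
#: worse (or leaves the record at its floor/ceiling).
WORSENINGS = [
    lambda r: dict(age=min(r.age + 10, 100)),
    lambda r: dict(systolic_bp=max(r.systolic_bp - 20, 40.0)),
    lambda r: dict(pulse=min(r.pulse + 20, 250.0)),
    lambda r: dict(hemoglobin=max(r.hemoglobin - 2, 2.0)),
    lambda r: dict(urea=min(r.urea + 5, 100.0)),
    lambda r: dict(creatinine=min(r.creatinine + 60, 2500.0)),
    lambda r: dict(albumin=max(r.albumin - 6, 10.0)),
    lambda r: dict(inr=min(r.inr + 1, 20.0)),
    lambda r: dict(gcs=max(r.gcs - 2, 3)),
    lambda r: dict(asa=min(r.asa + 1, 5)),
    lambda r: dict(general_condition="poor"),
    lambda r: dict(melena=True),
    lambda r: dict(syncope=True),
    lambda r: dict(liver_disease=True),
    lambda r: dict(cirrhosis=True, liver_disease=True),
    lambda r: dict(heart_failure=True),
    lambda r: dict(ischemic_heart_disease=True),
    lambda r: dict(renal_failure=True),
    lambda r: dict(liver_failure=True),
    lambda r: dict(metastatic_or_disseminated_malignancy=True),
    lambda r: dict(other_major_comorbidity=True),
]


@given(records(), st.integers(0, len(WORSENINGS) - 1))
@settings(max_examples=500, derandomize=True, deadline=None)
def test_worsening_one_component_never_lowers_risk(rec, idx):
    """Additive scores never decrease, the T-score never increases, when a
    single risk component is made worse with all others held fixed."""
    worse = PatientRecord(**{**rec.model_dump(), **WORSENINGS[idx](rec)})
    before, after = score_all(rec), score_all(worse)
    for system in SYSTEM_ORDER:
        if SYSTEMS[system].direction == "higher_is_worse":
            assert after[system].total >= before[system].total
        else:
            assert after[system].total <= before[system].total
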