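"""Six endoscopy-independent risk scores for upper-GI bleeding.

Implements ABC, AIMS65, Glasgow-Blatchford (GBS), MAP(ASH), pre-endoscopic
Rockall (pRS) and T-score exactly as published, against the canonical-unit
:class:`~ugibrisk.patient_model.PatientRecord`.  Five of the six award points
for risk markers (higher total = higher risk); the T-score grades each
component 1-3 with 3 the healthiest, so LOWER totals mean higher risk.

"Altered mental status" has no stored flag: each score derives it from the
Glasgow Coma Scale at its own threshold (AIMS65 uses GCS < 14; MAP(ASH) and
ABC use GCS < 15).

:func:`enumerate_rubric` is a brute-force oracle: it cross-multiplies every
component's attainable point values and returns the set of attainable totals,
so the published score ranges can be verified by exhaustion rather than
trusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

from .patient_model import PatientRecord, Sex, GeneralCondition

HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"


@dataclass(frozen=True)
class ScoreSystemSpec:
    """Metadata for one scoring system: attainable range and risk direction."""

    name: str
    min_total: int
    max_total: int
    direction: str


SYSTEMS: dict[str, ScoreSystemSpec] = {
    "ABC": ScoreSystemSpec("ABC", 0, 18, HIGHER_IS_WORSE),
    "AIMS65": ScoreSystemSpec("AIMS65", 0, 5, HIGHER_IS_WORSE),
    "GBS": ScoreSystemSpec("GBS", 0, 23, HIGHER_IS_WORSE),
    "MAPASH": ScoreSystemSpec("MAPASH", 0, 9, HIGHER_IS_WORSE),
    "PRS": ScoreSystemSpec("PRS", 0, 7, HIGHER_IS_WORSE),
    "TSCORE": ScoreSystemSpec("TSCORE", 4, 12, LOWER_IS_WORSE),
}

#: Canonical presentation order for tables.
SYSTEM_ORDER: tuple[str, ...] = ("ABC", "AIMS65", "GBS", "MAPASH", "PRS", "TSCORE")


@dataclass(frozen=True)
class ScoreResult:
    system: str
    total: int
    components: dict[str, int]

    def __post_init__(self):
        spec = SYSTEMS[self.system]
        assert self.total == sum(self.components.values())
        assert spec.min_total <= self.total <= spec.max_total


def _result(system: str, components: dict[str, int]) -> ScoreResult:
    return ScoreResult(system=system, total=sum(components.values()), components=components)


def score_aims65(rec: PatientRecord) -> ScoreResult:
    """AIMS65: one point each for low Albumin, INR > 1.5, altered Mental
    status (GCS < 14), low Systolic pressure, age > 65."""
    c = {
        "albumin<3.0g/dL": int(rec.albumin < 30.0),
        "inr>1.5": int(rec.inr > 1.5),
        "gcs<14": int(rec.gcs < 14),
        "sbp<90": int(rec.systolic_bp < 90.0),
        "age>65": int(rec.age > 65),
    }
    return _result("AIMS65", c)


def _gbs_urea(urea: float) -> int:
    if urea >= 25.0:
        return 6
    if urea >= 10.0:
        return 4
    if urea >= 8.0:
        return 3
    if urea >= 6.5:
        return 2
    return 0


def _gbs_hemoglobin(hb: float, sex: Sex) -> int:
    if sex is Sex.male:
        if hb < 10.0:
            return 6
        if hb < 12.0:
            return 3
        if hb < 13.0:
            return 1
        return 0
    if hb < 10.0:
        return 6
    if hb < 12.0:
        return 1
    return 0


def _gbs_sbp(sbp: float) -> int:
    if sbp < 90.0:
        return 3
    if sbp < 100.0:
        return 2
    if sbp < 110.0:
        return 1
    return 0


def score_gbs(rec: PatientRecord) -> ScoreResult:
    """Glasgow-Blatchford score (0-23): urea and sex-specific hemoglobin
    bands, vitals, presentation and comorbidity flags."""
    c = {
        "urea": _gbs_urea(rec.urea),
        "hemoglobin": _gbs_hemoglobin(rec.hemoglobin, rec.sex),
        "sbp": _gbs_sbp(rec.systolic_bp),
        "pulse>=100": int(rec.pulse >= 100.0),
        "melena": int(rec.melena),
        "syncope": 2 * int(rec.syncope),
        "liver_disease": 2 * int(rec.liver_disease),
        "heart_failure": 2 * int(rec.heart_failure),
    }
    return _result("GBS", c)


def _prs_age(age: int) -> int:
    if age >= 80:
        return 2
    if age >= 60:
        return 1
    return 0


def _prs_shock(sbp: float, pulse: float) -> int:
    # Hypotension dominates; tachycardia alone scores 1.
    if sbp < 100.0:
        return 2
    if pulse > 100.0:
        return 1
    return 0


def _prs_comorbidity(rec: PatientRecord) -> int:
    if rec.renal_failure or rec.liver_failure or rec.metastatic_or_disseminated_malignancy:
        return 3
    if rec.heart_failure or rec.ischemic_heart_disease or rec.other_major_comorbidity:
        return 2
    return 0


def score_prs(rec: PatientRecord) -> ScoreResult:
    """Pre-endoscopic (clinical) Rockall score (0-7): age, shock, comorbidity."""
    c = {
        "age": _prs_age(rec.age),
        "shock": _prs_shock(rec.systolic_bp, rec.pulse),
        "comorbidity": _prs_comorbidity(rec),
    }
    return _result("PRS", c)


_TSCORE_CONDITION = {
    GeneralCondition.poor: 1,
    GeneralCondition.intermediate: 2,
    GeneralCondition.good: 3,
}


def score_tscore(rec: PatientRecord) -> ScoreResult:
    """T-score (4-12): four components each graded 1-3; LOWER = higher risk.

    Middle bands are closed: pulse 90-110 and SBP 90-110 inclusive grade 2,
    hemoglobin 9-10 g/dL inclusive grades 2.
    """
    if rec.pulse > 110.0:
        pulse = 1
    elif rec.pulse >= 90.0:
        pulse = 2
    else:
        pulse = 3
    if rec.systolic_bp < 90.0:
        sbp = 1
    elif rec.systolic_bp <= 110.0:
        sbp = 2
    else:
        sbp = 3
    if rec.hemoglobin < 9.0:
        hb = 1
    elif rec.hemoglobin <= 10.0:
        hb = 2
    else:
        hb = 3
    c = {
        "general_condition": _TSCORE_CONDITION[rec.general_condition],
        "pulse": pulse,
        "sbp": sbp,
        "hemoglobin": hb,
    }
    return _result("TSCORE", c)


def score_mapash(rec: PatientRecord) -> ScoreResult:
    """MAP(ASH) (0-9): Mental status, Albumin, ASA, Systolic pressure,
    Heart rate, Hemoglobin."""
    c = {
        "gcs<15": int(rec.gcs < 15),
        "albumin<2.5g/dL": 2 * int(rec.albumin < 25.0),
        "asa>2": int(rec.asa > 2),
        "sbp<90": 2 * int(rec.systolic_bp < 90.0),
        "pulse>100": int(rec.pulse > 100.0),
        "hemoglobin<10g/dL": 2 * int(rec.hemoglobin < 10.0),
    }
    return _result("MAPASH", c)


def _abc_age(age: int) -> int:
    if age >= 75:
        return 2
    if age >= 60:
        return 1
    return 0


def _abc_creatinine(creatinine: float) -> int:
    if creatinine > 150.0:
        return 2
    if 100.0 <= creatinine <= 150.0:
        return 1
    return 0


def _abc_asa(asa: int) -> int:
    if asa >= 4:
        return 3
    if asa == 3:
        return 1
    return 0


def score_abc(rec: PatientRecord) -> ScoreResult:
    """ABC score (0-18): Age, Blood tests, Comorbidities."""
    c = {
        "age": _abc_age(rec.age),
        "urea>10": int(rec.urea > 10.0),
        "albumin<30g/L": 2 * int(rec.albumin < 30.0),
        "creatinine": _abc_creatinine(rec.creatinine),
        "gcs<15": 2 * int(rec.gcs < 15),
        "cirrhosis": 2 * int(rec.cirrhosis),
        "disseminated_malignancy": 4 * int(rec.metastatic_or_disseminated_malignancy),
        "asa": _abc_asa(rec.asa),
    }
    return _result("ABC", c)


SCORERS: dict[str, Callable[[PatientRecord], ScoreResult]] = {
    "ABC": score_abc,
    "AIMS65": score_aims65,
    "GBS": score_gbs,
    "MAPASH": score_mapash,
    "PRS": score_prs,
    "TSCORE": score_tscore,
}


def score_all(rec: PatientRecord) -> dict[str, ScoreResult]:
    """Apply all six scorers to one record."""
    return {name: SCORERS[name](rec) for name in SYSTEM_ORDER}


#: Attainable point values per component, per rubric.  Each component is
#: treated independently; the cross-product over these grids is the search
#: space for :func:`enumerate_rubric`.
RUBRIC_COMPONENT_OPTIONS: dict[str, dict[str, tuple[int, ...]]] = {
    "AIMS65": {
        "albumin": (0, 1),
        "inr": (0, 1),
        "mental_status": (0, 1),
        "sbp": (0, 1),
        "age": (0, 1),
    },
    "GBS": {
        "urea": (0, 2, 3, 4, 6),
        "hemoglobin": (0, 1, 3, 6),  # union of the men's and women's bands
        "sbp": (0, 1, 2, 3),
        "pulse": (0, 1),
        "melena": (0, 1),
        "syncope": (0, 2),
        "liver_disease": (0, 2),
        "heart_failure": (0, 2),
    },
    "PRS": {
        "age": (0, 1, 2),
        "shock": (0, 1, 2),
        "comorbidity": (0, 2, 3),
    },
    "TSCORE": {
        "general_condition": (1, 2, 3),
        "pulse": (1, 2, 3),
        "sbp": (1, 2, 3),
        "hemoglobin": (1, 2, 3),
    },
    "MAPASH": {
        "mental_status": (0, 1),
        "albumin": (0, 2),
        "asa": (0, 1),
        "sbp": (0, 2),
        "pulse": (0, 1),
        "hemoglobin": (0, 2),
    },
    "ABC": {
        "age": (0, 1, 2),
        "urea": (0, 1),
        "albumin": (0, 2),
        "creatinine": (0, 1, 2),
        "mental_status": (0, 2),
        "cirrhosis": (0, 2),
        "disseminated_malignancy": (0, 4),
        "asa": (0, 1, 3),
    },
}


def enumerate_rubric(system: str) -> set[int]:
    """Exhaustively enumerate every attainable total for one rubric.

    Cross-multiplies each component's possible point awards and sums; the
    result's max/min must equal the system's published range.
    """
    try:
        grids = RUBRIC_COMPONENT_OPTIONS[system]
    except KeyError:
        raise ValueError(f"unknown scoring system: {system!r}") from None
    return {sum(combo) for combo in itertools.product(*grids.values())}


def rubric_combination_count(system: str) -> int:
    """Number of component-band combinations enumerated for one rubric."""
    grids = RUBRIC_COMPONENT_OPTIONS[system]
    n = 1
    for options in grids.values():
        n *= len(options)
    return n
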