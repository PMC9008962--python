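"""Canonical patient-admission model and tabular cohort ingest.

One admission is a :class:`PatientRecord` holding every clinical variable the
six pre-endoscopy upper-GI-bleeding risk scores consume, stored in a single
set of canonical units (albumin g/L, hemoglobin g/dL, urea mmol/L, creatinine
umol/L).  Scorers never convert units; conversion, when needed, happens once
at ingest.

Cohorts arrive as CSV (one row per admission, header row).  Ingest is strict:
a row with a missing required field or a value outside physiologic sanity
bounds is rejected and counted, never clamped or imputed.  The age-65 boundary
splits a cohort into an elderly (>= 65) and a younger (< 65) stratum.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

ELDERLY_AGE = 65

#: Physiologic sanity bounds per numeric field, canonical units.  Values
#: outside these are treated as data errors at ingest (rejection, not
#: clamping).  Override per-call via ``read_cohort(bounds=...)``.
SANITY_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18, 110),
    "systolic_bp": (40.0, 260.0),
    "pulse": (20.0, 250.0),
    "hemoglobin": (2.0, 22.0),
    "urea": (0.5, 100.0),
    "creatinine": (10.0, 2500.0),
    "albumin": (10.0, 60.0),
    "inr": (0.5, 20.0),
    "gcs": (3, 15),
    "asa": (1, 5),
}

#: Multiplicative conversions into canonical units, keyed by (field, unit).
UNIT_CONVERSIONS: dict[tuple[str, str], float] = {
    ("hemoglobin", "g/L"): 0.1,       # -> g/dL
    ("albumin", "g/dL"): 10.0,        # -> g/L
    ("urea", "mg/dL"): 1.0 / 2.8,     # BUN mg/dL -> mmol/L
    ("creatinine", "mg/dL"): 88.4,    # -> umol/L
}


class Sex(str, Enum):
    male = "male"
    female = "female"


class GeneralCondition(str, Enum):
    """Subjective triage grade used by the T-score."""

    poor = "poor"
    intermediate = "intermediate"
    good = "good"


class Stratum(str, Enum):
    elderly = "elderly"
    younger = "younger"


class PatientRecord(BaseModel):
    """One admission's raw clinical variables in canonical units."""

    model_config = ConfigDict(frozen=True)

    age: int
    sex: Sex
    systolic_bp: float            # mmHg
    pulse: float                  # beats/min
    hemoglobin: float             # g/dL
    urea: float                   # mmol/L
    creatinine: float             # umol/L
    albumin: float                # g/L
    inr: float
    gcs: int                      # Glasgow Coma Scale, 3-15
    asa: int                      # ASA physical-status class, 1-5
    general_condition: GeneralCondition
    melena: bool
    syncope: bool
    liver_disease: bool
    cirrhosis: bool
    heart_failure: bool
    ischemic_heart_disease: bool
    renal_failure: bool
    liver_failure: bool
    metastatic_or_disseminated_malignancy: bool
    other_major_comorbidity: bool

    @field_validator(*SANITY_BOUNDS.keys())
    @classmethod
    def _within_sanity_bounds(cls, v, info):
        lo, hi = SANITY_BOUNDS[info.field_name]
        if not (lo <= v <= hi):
            raise ValueError(
                f"{info.field_name}={v!r} outside sanity bounds [{lo}, {hi}]"
            )
        return v

    @model_validator(mode="after")
    def _cirrhosis_implies_liver_disease(self):
        if self.cirrhosis and not self.liver_disease:
            raise ValueError("cirrhosis implies liver_disease")
        return self


class OutcomeLabels(BaseModel):
    """Binary 30-day clinical endpoints for one admission."""

    model_config = ConfigDict(frozen=True)

    death_30d: bool
    intervention: bool
    rebleeding: bool
    icu_admission: bool


OUTCOMES: tuple[str, ...] = ("death_30d", "intervention", "rebleeding", "icu_admission")


class CohortRow(BaseModel):
    """A validated admission: record, outcome labels and derived age stratum."""

    model_config = ConfigDict(frozen=True)

    record: PatientRecord
    outcomes: OutcomeLabels
    stratum: Stratum

    @model_validator(mode="after")
    def _stratum_consistent(self):
        expected = Stratum.elderly if self.record.age >= ELDERLY_AGE else Stratum.younger
        if self.stratum != expected:
            raise ValueError(
                f"stratum {self.stratum.value!r} inconsistent with age {self.record.age}"
            )
        return self


def make_row(record: PatientRecord, outcomes: OutcomeLabels) -> CohortRow:
    """Build a CohortRow with the stratum derived from age (65 -> elderly)."""
    stratum = Stratum.elderly if record.age >= ELDERLY_AGE else Stratum.younger
    return CohortRow(record=record, outcomes=outcomes, stratum=stratum)


class ExclusionReport(BaseModel):
    """Audit trail of listwise row exclusions during ingest."""

    n_input: int
    n_retained: int
    n_excluded: int
    reasons: dict[str, int]

    @property
    def retention(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2))


RECORD_FIELDS: tuple[str, ...] = tuple(PatientRecord.model_fields)
REQUIRED_COLUMNS: tuple[str, ...] = RECORD_FIELDS + OUTCOMES

_BOOL_FIELDS = tuple(
    name for name, f in PatientRecord.model_fields.items() if f.annotation is bool
) + OUTCOMES


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "y"}:
        return True
    if s in {"false", "0", "no", "n"}:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    max_reject_fraction: float = 0.5,
) -> tuple[list[CohortRow], ExclusionReport]:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row (RFC-4180, UTF-8).
    column_map
        Optional mapping from file column names to canonical field names.
    units
        Optional mapping field -> source unit (e.g. ``{"hemoglobin": "g/L"}``);
        values are converted into canonical units before validation.
    bounds
        Per-field sanity-bound overrides used for row rejection.
    max_reject_fraction
        Hard error if more than this fraction of rows is rejected.

    Returns
    -------
    (rows, report)
        Validated :class:`CohortRow` list and an :class:`ExclusionReport`
        counting rejected rows by reason (``missing:<field>``,
        ``bounds:<field>``, ``invalid:<field>``, ``invariant``).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns after mapping: {missing_cols}")

    eff_bounds = dict(SANITY_BOUNDS)
    if bounds:
        eff_bounds.update(bounds)

    rows: list[CohortRow] = []
    reasons: dict[str, int] = {}

    def reject(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    for rec in df.to_dict(orient="records"):
        reason = None
        values: dict[str, object] = {}
        for field in REQUIRED_COLUMNS:
            v = rec[field]
            if v is None or (isinstance(v, float) and pd.isna(v)) or (
                isinstance(v, str) and not v.strip()
            ):
                reason = f"missing:{field}"
                break
            if field in _BOOL_FIELDS:
                try:
                    values[field] = _coerce_bool(v)
                except ValueError:
                    reason = f"invalid:{field}"
                    break
                continue
            if field in eff_bounds:
                try:
                    x = float(v)
                except (TypeError, ValueError):
                    reason = f"invalid:{field}"
                    break
                if units and field in units:
                    factor = UNIT_CONVERSIONS.get((field, units[field]))
                    if factor is None:
                        raise ValueError(
                            f"no conversion for {field} from unit {units[field]!r}"
                        )
                    x *= factor
                lo, hi = eff_bounds[field]
                if not (lo <= x <= hi):
                    reason = f"bounds:{field}"
                    break
                values[field] = x
            else:
                values[field] = v
        if reason is None:
            try:
                record = PatientRecord(
                    **{k: values[k] for k in RECORD_FIELDS}
                )
                outcomes = OutcomeLabels(**{k: values[k] for k in OUTCOMES})
                rows.append(make_row(record, outcomes))
            except Exception:
                reason = "invariant"
        if reason is not None:
            reject(reason)

    n_input = len(df)
    report = ExclusionReport(
        n_input=n_input,
        n_retained=len(rows),
        n_excluded=n_input - len(rows),
        reasons=reasons,
    )
    if n_input and report.n_excluded / n_input > max_reject_fraction:
        raise ValueError(
            f"{report.n_excluded}/{n_input} rows rejected "
            f"(> max_reject_fraction={max_reject_fraction}); reasons: {reasons}"
        )
    return rows, report


def cohort_to_frame(cohort: Sequence[CohortRow]) -> pd.DataFrame:
    """Flatten a cohort into one DataFrame row per admission."""
    out = []
    for row in cohort:
        d = row.record.model_dump()
        d["sex"] = row.record.sex.value
        d["general_condition"] = row.record.general_condition.value
        d.update(row.outcomes.model_dump())
        d["stratum"] = row.stratum.value
        out.append(d)
    columns = list(REQUIRED_COLUMNS) + ["stratum"]
    return pd.DataFrame(out, columns=columns)


def write_cohort(cohort: Sequence[CohortRow], path: str | Path) -> None:
    """Write a cohort to CSV in canonical units (round-trips exactly)."""
    cohort_to_frame(cohort).drop(columns=["stratum"]).to_csv(path, index=False)


def stratify(cohort: Sequence[CohortRow]) -> tuple[list[CohortRow], list[CohortRow]]:
    """Partition a cohort at age 65 into (elderly, younger); 65 is elderly."""
    elderly = [r for r in cohort if r.stratum is Stratum.elderly]
    younger = [r for r in cohort if r.stratum is Stratum.younger]
    return elderly, younger
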