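# ugibrisk

Risk stratification for upper gastrointestinal bleeding (UGIB) without
endoscopy: six pre-endoscopy scoring systems — **ABC**, **AIMS65**,
**Glasgow-Blatchford (GBS)**, **MAP(ASH)**, **pre-endoscopic Rockall (pRS)**
and **T-score** — plus the ROC machinery used to compare their prognostic
accuracy for 30-day death, hospital-based intervention, rebleeding and ICU
admission, in elderly (age ≥ 65) versus younger adult cohorts.

The package is aimed at clinical epidemiologists validating admission risk
scores on tabular cohorts: it computes exact rubric totals from canonical-unit
patient records, empirical AUCs with DeLong variance, paired and unpaired
DeLong tests for AUC differences, Youden-index operating points with exact
binomial CIs, and ships a synthetic two-stratum cohort generator so the whole
pipeline runs end to end without access to hospital data.

## Core statistics

The empirical AUC is the normalized Mann–Whitney statistic with the half-tie
kernel,

    AUC = (1 / mn) Σᵢ Σⱼ ψ(Xᵢ, Yⱼ),   ψ = 1 if X > Y, ½ if X = Y, 0 if X < Y,

over positive scores X and negative scores Y. Its variance and the covariance
of two AUCs on the same patients come from DeLong's structural components
(V₁₀, V₀₁), giving the comparison statistic

    z = (A₁ − A₂) / √(V₁ + V₂ − 2C),

with C = 0 for disjoint cohorts. Operating points maximize the Youden index
J = sensitivity + specificity − 1; AUCs are banded as poor (0.5, 0.7], fair
(0.7, 0.9] or good (> 0.9). The T-score is the one lower-is-worse system and
is negated internally before any ROC computation.

The synthetic generator draws one latent severity L ~ N(0, 1) per patient;
outcomes are Bernoulli(logistic(α + βL)) with α solved so marginal prevalence
matches the configured rates exactly, and covariates drift with L in their
risky direction while preserving configured medians and IQRs. Defaults
reproduce the structure of a published 530-elderly / 730-younger UGIB cohort.
See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
from ugibrisk import synthetic_cohort, pipeline
from ugibrisk.risk_scores import score_all
from ugibrisk.patient_model import stratify

cohort = synthetic_cohort.generate(synthetic_cohort.default_config(seed=1))
print(len(cohort), [len(s) for s in stratify(cohort)])
# 1260 [530, 730]

table = pipeline.run_between_group(cohort, "death_30d")
print(pipeline.between_table_frame(table)[
    ["system", "elderly_auc", "younger_auc", "p_between"]].to_string(index=False))
```

prints

```
system         elderly_auc         younger_auc p_between
   ABC 0.731 (0.655-0.806) 0.748 (0.643-0.853)     0.792
AIMS65 0.679 (0.597-0.761) 0.663 (0.551-0.774)     0.818
   GBS 0.689 (0.617-0.761) 0.743 (0.624-0.863)     0.449
MAPASH 0.692 (0.605-0.778) 0.719 (0.611-0.827)     0.695
   PRS 0.599 (0.505-0.692) 0.694 (0.580-0.808)     0.207
TSCORE 0.691 (0.616-0.767) 0.736 (0.614-0.859)     0.538
```

Each row is one scoring system's mortality discrimination: the empirical AUC
with its DeLong 95% CI in each age stratum, and the unpaired DeLong p-value
for the between-stratum difference (none significant here — the default
generator gives both strata the same mortality effect size; see
`calibrate_beta` to set stratum-specific discrimination).

Scoring a single admission:

```python
from ugibrisk.patient_model import PatientRecord

rec = PatientRecord(
    age=70, sex="male", systolic_bp=85.0, pulse=70.0, hemoglobin=14.0,
    urea=5.0, creatinine=80.0, albumin=25.0, inr=1.8, gcs=15, asa=1,
    general_condition="good", melena=False, syncope=False,
    liver_disease=False, cirrhosis=False, heart_failure=False,
    ischemic_heart_disease=False, renal_failure=False, liver_failure=False,
    metastatic_or_disseminated_malignancy=False, other_major_comorbidity=False,
)
print({s: r.total for s, r in score_all(rec).items()})
# {'ABC': 3, 'AIMS65': 4, 'GBS': 3, 'MAPASH': 2, 'PRS': 3, 'TSCORE': 10}
```

## Analysis scripts

The `analysis/` drivers run the full study sequence on the default synthetic
cohort and write tables under `results/` (large intermediates under
`scratch/`):

```bash
python analysis/01_simulate_cohort.py     # cohort + per-stratum summary
python analysis/02_score_cohort.py        # six score totals per admission
python analysis/03_between_group_roc.py   # per-outcome elderly-vs-younger tables
python analysis/04_within_group_pairwise.py  # 6x6 paired DeLong p matrices
```

A `ugibrisk` console command exposes the same steps
(`simulate` / `score` / `compare` / `report`) for CSV cohorts.

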