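"""Synthetic two-stratum upper-GI-bleeding cohorts.

Real UGIB admission data are hospital-held and not deposited, so every
downstream stage (scoring, ROC, AUC comparison) is exercised on synthetic
cohorts that reproduce the published cohort's structure: 530 elderly
(age >= 65) and 730 younger admissions, with stratum-specific comorbidity
prevalences, lab/vital medians and IQRs, and outcome rates (e.g. 30-day
death 44/530 elderly vs 24/730 younger).

Generative model
----------------
Each patient carries one latent severity L ~ N(0, 1).

* Outcomes are Bernoulli(logistic(alpha_o + beta_o * L)); the intercept
  alpha_o is solved numerically (Gauss-Hermite quadrature + Brent root find)
  so the marginal prevalence matches the configured rate exactly.  beta_o is
  the per-outcome, per-stratum discrimination: beta = 0 makes the outcome
  independent of every covariate (expected AUC 0.5 for every score).
* Continuous covariates are normal (vitals) or log-normal (labs) with
  location/scale solved from the configured median and IQR; the Gaussian
  kernel is rho * d * L + sqrt(1 - rho^2) * eps, where d = +1 when higher
  values are riskier (urea, creatinine, pulse, INR) and -1 otherwise
  (SBP, hemoglobin, albumin), so marginal median/IQR are preserved while
  sicker patients drift in the risky direction.  Out-of-bounds draws are
  resampled, never clamped.
* Binary comorbidities and presentation flags are Bernoulli with log-odds
  alpha_c + eta * L, with alpha_c again solved to match the configured
  marginal prevalence.
* GCS, ASA class and the T-score "general condition" grade are ordinal
  transforms of latent severity (quantile cuts on a correlated Gaussian).

Same config (including its seed) => bit-identical cohort.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .patient_model import (
    SANITY_BOUNDS,
    CohortRow,
    GeneralCondition,
    OutcomeLabels,
    OUTCOMES,
    PatientRecord,
    Sex,
    Stratum,
    cohort_to_frame,
    make_row,
)
from .risk_scores import SCORERS, SYSTEMS
from .roc_delong import auc_value, orient

_Z75 = float(norm.ppf(0.75))
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(64)

#: Continuous covariates and whether higher values indicate more severe
#: bleeding physiology.
RISK_DIRECTION: dict[str, int] = {
    "systolic_bp": -1,
    "pulse": +1,
    "hemoglobin": -1,
    "urea": +1,
    "creatinine": +1,
    "albumin": -1,
    "inr": +1,
}

COMORBIDITIES: tuple[str, ...] = (
    "cirrhosis",
    "liver_disease",
    "renal_failure",
    "liver_failure",
    "metastatic_or_disseminated_malignancy",
    "heart_failure",
    "ischemic_heart_disease",
    "other_major_comorbidity",
)


class CovariateSpec(BaseModel):
    """Marginal location/scale for one continuous covariate (canonical units)."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    iqr: float = Field(gt=0)
    dist: Literal["normal", "lognormal"] = "lognormal"
    loading: float = Field(default=0.55, ge=0.0, lt=1.0)


class StratumConfig(BaseModel):
    """One age stratum: size, demographics, marginals and effect sizes."""

    n: int = Field(ge=1)
    age_range: tuple[int, int]
    age_mean: float
    age_sd: float = Field(gt=0)
    p_male: float = Field(ge=0, le=1)
    covariates: dict[str, CovariateSpec]
    comorbidity_prevalence: dict[str, float]
    presentation_prevalence: dict[str, float]
    p_altered_mental: float = Field(ge=0, le=1)
    asa_probs: tuple[float, float, float, float, float]
    outcome_prevalence: dict[str, float]
    discrimination: dict[str, float]

    @model_validator(mode="after")
    def _check(self):
        for name in RISK_DIRECTION:
            if name not in self.covariates:
                raise ValueError(f"missing covariate spec: {name}")
        for d in (self.comorbidity_prevalence, self.presentation_prevalence,
                  self.outcome_prevalence):
            for k, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence out of [0,1]: {k}={p}")
        for o in OUTCOMES:
            if o not in self.outcome_prevalence:
                raise ValueError(f"missing outcome prevalence: {o}")
            if self.discrimination.get(o, 0.0) < 0.0:
                raise ValueError(f"discrimination must be >= 0 for {o}")
        if abs(sum(self.asa_probs) - 1.0) > 1e-9:
            raise ValueError("asa_probs must sum to 1")
        if (self.comorbidity_prevalence["cirrhosis"]
                > self.comorbidity_prevalence["liver_disease"]):
            raise ValueError("cirrhosis prevalence cannot exceed liver_disease")
        return self


class CohortConfig(BaseModel):
    """Full two-stratum generator configuration; a pure function of this
    object (seed included) defines the cohort."""

    elderly: StratumConfig
    younger: StratumConfig
    comorbidity_loading: float = Field(default=0.8, ge=0)
    gcs_loading: float = Field(default=0.6, ge=0, lt=1)
    asa_loading: float = Field(default=0.6, ge=0, lt=1)
    condition_loading: float = Field(default=0.7, ge=0, lt=1)
    condition_quantiles: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    seed: int = 0


def _frac(count: int, n: int) -> float:
    return count / n


def default_config(seed: int = 0) -> CohortConfig:
    """Defaults reproducing the published cohort's structure.

    Sizes 530/730; outcome prevalences from printed counts (death 44 & 24,
    intervention 240 & 304, rebleeding 112 & 60; ICU 19 & 13 inferred from
    the reported sensitivity denominators, an assumption); covariate medians
    and IQRs from the published per-stratum table (hemoglobin converted
    g/L -> g/dL).  INR marginals and some flag prevalences are not printed
    and are set to clinically typical values (see docs/methods.md).
    """
    elderly = StratumConfig(
        n=530,
        age_range=(65, 89),
        age_mean=72.9,
        age_sd=6.1,
        p_male=_frac(350, 530),
        covariates={
            "systolic_bp": CovariateSpec(median=124, iqr=28, dist="normal"),
            "pulse": CovariateSpec(median=79, iqr=18, dist="normal"),
            "hemoglobin": CovariateSpec(median=8.9, iqr=4.3),
            "urea": CovariateSpec(median=9.7, iqr=10.1),
            "creatinine": CovariateSpec(median=82, iqr=41),
            "albumin": CovariateSpec(median=33.7, iqr=8.45),
            "inr": CovariateSpec(median=1.2, iqr=0.4),
        },
        comorbidity_prevalence={
            "cirrhosis": _frac(52, 530),
            "liver_disease": _frac(52, 530) + 0.03,
            "renal_failure": _frac(56, 530),
            "liver_failure": 0.03,
            "metastatic_or_disseminated_malignancy": _frac(46, 530) / 2,
            "heart_failure": _frac(16, 530),
            "ischemic_heart_disease": _frac(52, 530),
            "other_major_comorbidity": 0.35,
        },
        presentation_prevalence={"melena": 0.70, "syncope": 0.08},
        p_altered_mental=0.10,
        asa_probs=(0.05, 0.30, 0.45, 0.17, 0.03),
        outcome_prevalence={
            "death_30d": _frac(44, 530),
            "intervention": _frac(240, 530),
            "rebleeding": _frac(112, 530),
            "icu_admission": _frac(19, 530),
        },
        discrimination={"death_30d": 1.2, "intervention": 0.7,
                        "rebleeding": 0.8, "icu_admission": 1.1},
    )
    younger = StratumConfig(
        n=730,
        age_range=(18, 64),
        age_mean=48.7,
        age_sd=12.2,
        p_male=_frac(573, 730),
        covariates={
            "systolic_bp": CovariateSpec(median=120, iqr=24, dist="normal"),
            "pulse": CovariateSpec(median=82, iqr=22.5, dist="normal"),
            "hemoglobin": CovariateSpec(median=10.25, iqr=4.5),
            "urea": CovariateSpec(median=7.9, iqr=6.35),
            "creatinine": CovariateSpec(median=73, iqr=27),
            "albumin": CovariateSpec(median=37.25, iqr=9.08),
            "inr": CovariateSpec(median=1.1, iqr=0.3),
        },
        comorbidity_prevalence={
            "cirrhosis": _frac(108, 730),
            "liver_disease": _frac(108, 730) + 0.03,
            "renal_failure": _frac(10, 730),
            "liver_failure": 0.02,
            "metastatic_or_disseminated_malignancy": _frac(118, 730) / 2,
            "heart_failure": _frac(2, 730),
            "ischemic_heart_disease": _frac(28, 730),
            "other_major_comorbidity": 0.18,
        },
        presentation_prevalence={"melena": 0.70, "syncope": 0.06},
        p_altered_mental=0.04,
        asa_probs=(0.30, 0.35, 0.25, 0.08, 0.02),
        outcome_prevalence={
            "death_30d": _frac(24, 730),
            "intervention": _frac(304, 730),
            "rebleeding": _frac(60, 730),
            "icu_admission": _frac(13, 730),
        },
        discrimination={"death_30d": 1.2, "intervention": 0.7,
                        "rebleeding": 0.8, "icu_admission": 1.1},
    )
    return CohortConfig(elderly=elderly, younger=younger, seed=seed)


def solve_logistic_intercept(beta: float, p: float) -> float:
    """alpha such that E_L[logistic(alpha + beta * L)] = p for L ~ N(0,1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {p}")

    def marginal(a: float) -> float:
        return float(
            np.sum(_GH_W * expit(a + beta * np.sqrt(2.0) * _GH_X)) / np.sqrt(np.pi)
        ) - p

    try:
        return brentq(marginal, -60.0, 60.0, xtol=1e-12)
    except ValueError as e:  # pragma: no cover - only for absurd beta/p
        raise ValueError(
            f"infeasible prevalence {p} at effect size {beta}"
        ) from e


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    # IQR = 2 * median * sinh(z75 * sigma)
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return float(np.log(median)), sigma


def _normal_params(median: float, iqr: float) -> tuple[float, float]:
    return median, iqr / (2.0 * _Z75)


def _draw_covariate_values(
    rng: np.random.Generator,
    name: str,
    spec: CovariateSpec,
    latent: np.ndarray,
) -> np.ndarray:
    rho = spec.loading
    direction = RISK_DIRECTION[name]
    if spec.dist == "lognormal":
        mu, sigma = _lognormal_params(spec.median, spec.iqr)
    else:
        mu, sigma = _normal_params(spec.median, spec.iqr)
    lo, hi = SANITY_BOUNDS[name]
    base = rho * direction * latent
    resid = np.sqrt(1.0 - rho * rho)
    n = latent.shape[0]
    values = np.empty(n)
    todo = np.arange(n)
    for _ in range(500):
        z = base[todo] + resid * rng.standard_normal(todo.size)
        v = np.exp(mu + sigma * z) if spec.dist == "lognormal" else mu + sigma * z
        ok = (v >= lo) & (v <= hi)
        values[todo[ok]] = v[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return values
    raise RuntimeError(f"could not sample {name} within sanity bounds")


def _draw_ages(rng, cfg: StratumConfig) -> np.ndarray:
    lo, hi = cfg.age_range
    ages = np.empty(cfg.n, dtype=int)
    todo = np.arange(cfg.n)
    for _ in range(500):
        a = np.rint(cfg.age_mean + cfg.age_sd * rng.standard_normal(todo.size)).astype(int)
        ok = (a >= lo) & (a <= hi)
        ages[todo[ok]] = a[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return ages
    raise RuntimeError("could not sample ages within range")


def _draw_bernoulli(rng, latent, p: float, eta: float) -> np.ndarray:
    if p <= 0.0:
        return np.zeros_like(latent, dtype=bool)
    if p >= 1.0:
        return np.ones_like(latent, dtype=bool)
    alpha = solve_logistic_intercept(eta, p)
    return rng.random(latent.shape[0]) < expit(alpha + eta * latent)


def _correlated_gaussian(rng, latent, loading: float) -> np.ndarray:
    return loading * latent + np.sqrt(1.0 - loading * loading) * rng.standard_normal(
        latent.shape[0]
    )


_CONDITIONS = (GeneralCondition.good, GeneralCondition.intermediate, GeneralCondition.poor)


def _generate_stratum(
    rng: np.random.Generator, cfg: StratumConfig, top: CohortConfig
) -> list[CohortRow]:
    n = cfg.n
    latent = rng.standard_normal(n)
    ages = _draw_ages(rng, cfg)
    male = rng.random(n) < cfg.p_male

    cont = {
        name: _draw_covariate_values(rng, name, spec, latent)
        for name, spec in cfg.covariates.items()
    }

    # GCS: mostly 15; the altered tail deepens with latent severity.
    z_gcs = _correlated_gaussian(rng, latent, top.gcs_loading)
    gcs = np.full(n, 15, dtype=int)
    if cfg.p_altered_mental > 0:
        thr = norm.ppf(1.0 - cfg.p_altered_mental)
        altered = z_gcs > thr
        depth = (norm.cdf(z_gcs[altered]) - (1.0 - cfg.p_altered_mental)) / cfg.p_altered_mental
        gcs[altered] = np.clip(14 - np.floor(depth * 12.0).astype(int), 3, 14)

    z_asa = _correlated_gaussian(rng, latent, top.asa_loading)
    asa_cuts = norm.ppf(np.cumsum(cfg.asa_probs)[:-1])
    asa = np.searchsorted(asa_cuts, z_asa, side="right") + 1

    z_cond = _correlated_gaussian(rng, latent, top.condition_loading)
    q1, q2 = top.condition_quantiles
    cond_cuts = norm.ppf([q1, q2])
    cond_idx = np.searchsorted(cond_cuts, z_cond, side="right")

    eta = top.comorbidity_loading
    flags: dict[str, np.ndarray] = {}
    for name in COMORBIDITIES:
        if name == "liver_disease":
            continue
        flags[name] = _draw_bernoulli(rng, latent, cfg.comorbidity_prevalence[name], eta)
    p_cirr = cfg.comorbidity_prevalence["cirrhosis"]
    p_liver = cfg.comorbidity_prevalence["liver_disease"]
    p_extra = 0.0 if p_cirr >= p_liver else (p_liver - p_cirr) / (1.0 - p_cirr)
    extra_liver = _draw_bernoulli(rng, latent, p_extra, eta)
    flags["liver_disease"] = flags["cirrhosis"] | extra_liver

    melena = _draw_bernoulli(rng, latent, cfg.presentation_prevalence["melena"], eta)
    syncope = _draw_bernoulli(rng, latent, cfg.presentation_prevalence["syncope"], eta)

    outcome_draws: dict[str, np.ndarray] = {}
    for o in OUTCOMES:
        beta = cfg.discrimination.get(o, 0.0)
        p = cfg.outcome_prevalence[o]
        if p <= 0.0:
            outcome_draws[o] = np.zeros(n, dtype=bool)
        elif p >= 1.0:
            outcome_draws[o] = np.ones(n, dtype=bool)
        else:
            alpha = solve_logistic_intercept(beta, p)
            outcome_draws[o] = rng.random(n) < expit(alpha + beta * latent)

    rows: list[CohortRow] = []
    for i in range(n):
        record = PatientRecord(
            age=int(ages[i]),
            sex=Sex.male if male[i] else Sex.female,
            systolic_bp=float(cont["systolic_bp"][i]),
            pulse=float(cont["pulse"][i]),
            hemoglobin=float(cont["hemoglobin"][i]),
            urea=float(cont["urea"][i]),
            creatinine=float(cont["creatinine"][i]),
            albumin=float(cont["albumin"][i]),
            inr=float(cont["inr"][i]),
            gcs=int(gcs[i]),
            asa=int(asa[i]),
            general_condition=_CONDITIONS[cond_idx[i]],
            melena=bool(melena[i]),
            syncope=bool(syncope[i]),
            liver_disease=bool(flags["liver_disease"][i]),
            cirrhosis=bool(flags["cirrhosis"][i]),
            heart_failure=bool(flags["heart_failure"][i]),
            ischemic_heart_disease=bool(flags["ischemic_heart_disease"][i]),
            renal_failure=bool(flags["renal_failure"][i]),
            liver_failure=bool(flags["liver_failure"][i]),
            metastatic_or_disseminated_malignancy=bool(
                flags["metastatic_or_disseminated_malignancy"][i]
            ),
            other_major_comorbidity=bool(flags["other_major_comorbidity"][i]),
        )
        outcomes = OutcomeLabels(**{o: bool(outcome_draws[o][i]) for o in OUTCOMES})
        rows.append(make_row(record, outcomes))
    return rows


def generate(config: CohortConfig) -> list[CohortRow]:
    """Generate a full two-stratum cohort; pure function of the config."""
    ss = np.random.SeedSequence(config.seed)
    seed_e, seed_y = ss.spawn(2)
    rows = _generate_stratum(np.random.default_rng(seed_e), config.elderly, config)
    rows += _generate_stratum(np.random.default_rng(seed_y), config.younger, config)
    return rows


def _scores_for(rows: list[CohortRow], system: str) -> np.ndarray:
    scorer = SCORERS[system]
    return np.array([scorer(r.record).total for r in rows], dtype=float)


def calibrate_beta(
    config: CohortConfig,
    system: str,
    outcome: str,
    target_auc: float,
    n_calib: int = 5000,
    seed: int = 0,
    stratum: str = "pooled",
    tol: float = 0.01,
    max_beta: float = 16.0,
) -> float:
    """Find the discrimination beta at which `system` attains `target_auc`
    against `outcome`, by monotone bisection on simulated cohorts.

    Every candidate beta is evaluated on a cohort of size ``n_calib``
    regenerated from the same seed (common random numbers), so the simulated
    AUC is a deterministic, monotone-in-beta function and the search is a
    plain root bracket.
    """
    if not 0.5 <= target_auc < 0.99:
        raise ValueError("target_auc must be in [0.5, 0.99)")
    if target_auc == 0.5:
        return 0.0
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}")

    cfg = config.model_copy(deep=True)
    cfg.seed = seed
    if stratum == "pooled":
        cfg.elderly.n = max(1, n_calib // 2)
        cfg.younger.n = n_calib - cfg.elderly.n
    elif stratum == "elderly":
        cfg.elderly.n = n_calib
        cfg.younger.n = 1
    elif stratum == "younger":
        cfg.younger.n = n_calib
        cfg.elderly.n = 1
    else:
        raise ValueError(f"unknown stratum {stratum!r}")

    direction = SYSTEMS[system].direction

    def simulated_auc(beta: float) -> float:
        cfg.elderly.discrimination[outcome] = beta
        cfg.younger.discrimination[outcome] = beta
        rows = generate(cfg)
        if stratum != "pooled":
            rows = [r for r in rows if r.stratum.value == stratum]
        labels = np.array([getattr(r.outcomes, outcome) for r in rows], dtype=bool)
        scores = orient(_scores_for(rows, system), direction)
        return auc_value(scores, labels)

    lo, f_lo = 0.0, simulated_auc(0.0)
    hi = 1.0
    f_hi = simulated_auc(hi)
    while f_hi < target_auc:
        hi *= 2.0
        if hi > max_beta:
            raise ValueError(
                f"target AUC {target_auc} not attainable for {system} vs {outcome} "
                f"(AUC at beta={hi / 2} was {f_hi:.3f})"
            )
        f_hi = simulated_auc(hi)
    if f_lo > target_auc:
        raise ValueError("AUC at beta=0 already exceeds target; non-bracketing")

    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = simulated_auc(mid)
        if abs(f_mid - target_auc) <= tol:
            return mid
        if f_mid < target_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_CONT_FIELDS = tuple(RISK_DIRECTION)
_BINARY_SUMMARY = COMORBIDITIES + ("melena", "syncope")


def summarize(cohort: list[CohortRow]) -> pd.DataFrame:
    """Per-stratum medians (IQR), flag prevalences and outcome rates.

    Descriptive companion to the generator: compare against the config to
    check marginal fidelity.  One row per stratum; empty strata yield a row
    of NaNs with n = 0.
    """
    frame = cohort_to_frame(cohort)
    records = []
    for stratum in (Stratum.elderly.value, Stratum.younger.value):
        sub = frame[frame["stratum"] == stratum]
        row: dict[str, float] = {"stratum": stratum, "n": len(sub)}
        for f in _CONT_FIELDS:
            if len(sub):
                q1, q2, q3 = sub[f].quantile([0.25, 0.5, 0.75])
                row[f"{f}_median"], row[f"{f}_iqr"] = q2, q3 - q1
            else:
                row[f"{f}_median"] = row[f"{f}_iqr"] = float("nan")
        for f in _BINARY_SUMMARY + OUTCOMES:
            row[f"{f}_rate"] = sub[f].mean() if len(sub) else float("nan")
        records.append(row)
    return pd.DataFrame(records).set_index("stratum")
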