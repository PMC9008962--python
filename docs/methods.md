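# Methods

## Problem and scope

Upper gastrointestinal bleeding (UGIB) is triaged with pre-endoscopy risk
scores computed from admission vitals, labs, comorbidities and presentation.
This package implements six such scores — ABC, AIMS65, Glasgow-Blatchford
(GBS), MAP(ASH), pre-endoscopic Rockall (pRS) and T-score — together with the
statistical machinery used to compare their discrimination for binary
30-day endpoints (death, hospital-based intervention, rebleeding, ICU
admission) between an elderly (age ≥ 65) and a younger (18–64) stratum, and
among the six systems within a stratum.

Because admission-level hospital data of this kind are not publicly
deposited, the package ships a synthetic cohort generator that emulates the
joint structure of such a cohort; every analysis stage is exercised end to
end on generated data.

## Scoring rubrics

Each score is an integer sum of banded component points:

* **AIMS65** (0–5): albumin < 3.0 g/dL, INR > 1.5, GCS < 14, SBP < 90 mmHg,
  age > 65 — one point each.
* **GBS** (0–23): urea bands [6.5, 8) → 2, [8, 10) → 3, [10, 25) → 4,
  ≥ 25 → 6 mmol/L; hemoglobin (men) [12, 13) → 1, [10, 12) → 3, < 10 → 6,
  (women) [10, 12) → 1, < 10 → 6 g/dL; SBP [100, 110) → 1, [90, 100) → 2,
  < 90 → 3; pulse ≥ 100 → 1; melena 1; syncope 2; liver disease 2; heart
  failure 2.
* **pRS** (0–7): age [60, 80) → 1, ≥ 80 → 2; shock: SBP < 100 → 2 else
  pulse > 100 (with SBP ≥ 100) → 1; comorbidity: renal failure, liver
  failure or metastatic malignancy → 3, else heart failure, ischemic heart
  disease or other major comorbidity → 2 (highest tier only).
* **T-score** (4–12, **lower = higher risk**): general condition
  poor/intermediate/good → 1/2/3; pulse > 110 → 1, [90, 110] → 2, < 90 → 3;
  SBP < 90 → 1, [90, 110] → 2, > 110 → 3; hemoglobin < 9 → 1, [9, 10] → 2,
  > 10 → 3 g/dL.
* **MAP(ASH)** (0–9): GCS < 15 → 1; albumin < 2.5 g/dL → 2; ASA > 2 → 1;
  SBP < 90 → 2; pulse > 100 → 1; hemoglobin < 10 g/dL → 2.
* **ABC** (0–18): age [60, 75) → 1, ≥ 75 → 2; urea > 10 mmol/L → 1;
  albumin < 30 g/L → 2; creatinine [100, 150] → 1, > 150 μmol/L → 2;
  GCS < 15 → 2; cirrhosis 2; disseminated malignancy 4; ASA 3 → 1, ≥ 4 → 3.

Band-edge conventions that the original publications leave typographically
ambiguous were fixed once: half-open lab/vital bands for GBS; pRS age ≥ 80
for the 2-point band (so the bands partition all ages); pRS hypotension
dominating tachycardia; closed middle bands for the T-score; a closed
creatinine band [100, 150] for ABC; MAP(ASH)'s "hemoglobin < 10 g/L" and
AIMS65's "albumin < 3.0 mg/dl" read as g/dL (the printed units are not
survivable values).  "Altered mental status" is never stored; each score
derives it from the GCS at its own threshold (AIMS65 < 14, MAP(ASH) and
ABC < 15), and the GCS < 15 choice for ABC is a convention adopted here.

All records are stored in one canonical unit system (albumin g/L, hemoglobin
g/dL, urea mmol/L, creatinine μmol/L); unit conversion happens at ingest
only.  A record missing a field required by a system is an error for that
system, never a zero-point assumption; cohort ingest uses listwise exclusion
with a per-reason audit trail.

`enumerate_rubric` cross-multiplies every component's attainable point values
(sex-specific hemoglobin bands are merged into one option set) and returns
all attainable totals; the published maxima (5, 23, 7, 12, 9, 18) are
verified by this exhaustion rather than assumed.

## ROC, AUC and DeLong comparisons

The empirical AUC is the normalized Mann–Whitney statistic with the
half-tie kernel ψ(X, Y) = 1, ½, 0 for X > Y, X = Y, X < Y, computed via
midranks in O(N log N).  Sampling variance uses DeLong's structural
components: V₁₀(i) = meanⱼ ψ(Xᵢ, Yⱼ), V₀₁(j) = meanᵢ ψ(Xᵢ, Yⱼ),
Var = S₁₀/m + S₀₁/n (sample variances, ddof = 1).  Two scores on the same
patients are compared with z = (A₁ − A₂)/√(V₁ + V₂ − 2C), C from the sample
covariances of the paired components; scores on disjoint cohorts use C = 0.
All p-values are two-sided normal tails; no multiple-testing correction is
applied across the 15 pairwise comparisons (a Holm option exists upstream of
formatting but is off by default, matching common practice in this
literature).

The 95% CI for an AUC is the normal approximation A ± 1.96√V clamped to
[0, 1].  Operating points maximize the Youden index J = sens + spec − 1 over
thresholds at observed score values (positivity: oriented score ≥ threshold;
T-score totals are negated first so higher always means riskier).  Ties in J
resolve to the higher-sensitivity, then lower-threshold point.  Sensitivity
and specificity carry exact Clopper–Pearson binomial CIs.  Discrimination is
banded as non-informative (≤ 0.5), poor (0.5, 0.7], fair (0.7, 0.9], good
(> 0.9).

Degenerate inputs: a single-class label vector is an explicit error (AUC
undefined); fewer than two members of either class make the DeLong variance
undefined (error); an all-tied score vector yields the trivial operating
point with a warning; a zero-variance AUC difference yields p = 1 when the
AUCs are equal and an error otherwise.

## Synthetic cohort generator

One latent severity L ~ N(0, 1) per patient drives everything — the minimal
joint structure able to induce realistic score–outcome correlation:

* **Outcomes**: Bernoulli(logistic(α + βL)).  β ≥ 0 is the per-outcome,
  per-stratum discrimination; α is solved by 64-node Gauss–Hermite
  quadrature + Brent root finding so the marginal prevalence matches the
  configuration exactly.  β = 0 severs all outcome–covariate dependence.
* **Continuous covariates**: vitals normal, labs log-normal, location/scale
  solved from the configured median and IQR (log-normal
  σ = asinh(IQR/2·median)/z₀.₇₅).  The Gaussian kernel is
  ρ·d·L + √(1−ρ²)·ε with risk direction d = ±1 and default loading
  ρ = 0.55, chosen once so that composite scores can span the AUC range
  reported for real UGIB cohorts (up to ≈ 0.9); marginal median/IQR are
  unaffected by ρ.  Draws outside physiologic sanity bounds are resampled.
* **Binary flags** (comorbidities, melena, syncope): Bernoulli with
  log-odds α_c + ηL, η = 0.8 per SD of severity, α_c solved as above.
  Liver disease is the union of cirrhosis and an independent non-cirrhotic
  component, preserving the cirrhosis ⇒ liver-disease invariant.
* **Ordinal variables**: GCS is 15 except for a configurable altered-mental
  tail (deeper with severity); ASA class and the T-score general-condition
  grade are quantile cuts of Gaussians correlated with L (condition cut at
  tertiles by default).
* **Demographics**: truncated-normal ages (elderly 65–89, mean 72.9,
  SD 6.1; younger 18–64, mean 48.7, SD 12.2), Bernoulli sex.

Default marginals reproduce the published stratum table: sizes 530/730;
death 44/530 and 24/730; intervention 240/530 and 304/730; rebleeding
112/530 and 60/730; covariate medians/IQRs per stratum (hemoglobin converted
g/L → g/dL).  Values the table does not print were set once to clinically
typical levels and are plain config fields: ICU admission 19/530 and 13/730
(inferred from reported sensitivity denominators — an assumption, not a
published count); INR median 1.2/1.1; melena 0.70; syncope 0.08/0.06;
altered mental status 0.10/0.04; ASA category probabilities chosen to
reproduce the printed median (IQR) of 3 (1) and 2 (2); disseminated
malignancy taken as half of the printed "any malignancy"; ischemic heart
disease proxied by the printed PCI prevalence; default β of 1.2 (death),
1.1 (ICU), 0.8 (rebleeding), 0.7 (intervention) giving mid-range
discrimination.  `calibrate_beta` finds the β attaining a requested AUC for
a given system/outcome/stratum by bisection on cohorts regenerated under
common random numbers (deterministic, monotone in β), evaluating at
n = 5000 by default and stopping within ±0.01 of the target.

What the generator does **not** emulate: per-diagnosis endoscopic findings,
treatment pathways, survival times, secular trends, and any
outcome–covariate dependence beyond the single factor.  Passing tests
therefore demonstrate that the computational machinery is correct and
well-calibrated under a plausible joint model — not that any score performs
at a particular level on real patients.

## Verification design

* Rubric totals are checked against hand-worked admissions and by exhaustive
  enumeration of every band combination; property fuzzing (10⁴ random
  records) asserts range, integrality, component conservation and
  single-component monotonicity (additive scores never decrease, the
  T-score never increases, when one risk factor worsens).
* The rank-based AUC is compared with brute-force pair counting and scipy's
  Mann–Whitney U on random tied instances.
* The DeLong variance is validated against a 2000-replicate stratified
  bootstrap (agreement within 15% at n = 200), and both comparison tests
  against their nominal type-I error (rejection rate within [0.03, 0.07] at
  α = 0.05 over 1000 seeded null replicates, n = 300).
* Generator fidelity: marginal rates within 3 binomial SEs of the config;
  β = 0 yields chance-level AUC for every system and outcome; calibration to
  AUC 0.80 (GBS vs death) recovers 0.80 ± 0.03 on an independent seed.

Simulation sizes in the test suite (n = 200–8000, 1000 replicates) were
chosen as the smallest at which the checked tolerances are comfortably
inside sampling noise.

## Known limitations

* Between-group p-values assume the unpaired normal DeLong form; no
  continuity correction or exact small-sample test is offered.
* The generator's single-factor dependence cannot represent outcome-specific
  risk profiles (e.g. a score that predicts rebleeding but not death).
* pRS, a coarse 8-level score, saturates near AUC ≈ 0.85 under the default
  loadings; calibration targets above a system's ceiling raise an explicit
  error rather than silently undershooting.
* Scoring requires complete records; no imputation is provided by design.
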