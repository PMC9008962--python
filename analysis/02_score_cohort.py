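#!/usr/bin/env python
"""Score every admission with the six pre-endoscopy systems.

Reads the simulated cohort (regenerating it if 01 has not been run), applies
ABC, AIMS65, GBS, MAP(ASH), pRS and T-score to each admission, and writes the
wide score table to scratch/scores.csv plus per-stratum median totals to
results/score_medians.csv.
"""

from pathlib import Path

from ugibrisk import patient_model, pipeline, synthetic_cohort
from ugibrisk.risk_scores import SYSTEM_ORDER

ROOT = Path(__file__).resolve().parents[1]


def load_cohort():
    path = ROOT / "scratch" / "cohort.csv"
    if path.exists():
        rows, report = patient_model.read_cohort(path)
        print(f"loaded {report.n_retained} admissions from {path}")
        return rows
    print("scratch/cohort.csv missing; regenerating with seed 1")
    return synthetic_cohort.generate(synthetic_cohort.default_config(seed=1))


def main() -> None:
    cohort = load_cohort()
    frame = pipeline.score_frame(cohort)
    (ROOT / "scratch").mkdir(exist_ok=True)
    frame.to_csv(ROOT / "scratch" / "scores.csv", index=False)

    medians = frame.groupby("stratum")[list(SYSTEM_ORDER)].median()
    (ROOT / "results").mkdir(exist_ok=True)
    medians.to_csv(ROOT / "results" / "score_medians.csv")
    print("median totals per stratum:")
    print(medians.to_string())
    print("wrote scratch/scores.csv and results/score_medians.csv")


if __name__ == "__main__":
    main()
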