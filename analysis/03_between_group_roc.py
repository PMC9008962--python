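#!/usr/bin/env python
"""Elderly-vs-younger discrimination of the six systems, per outcome.

For each clinical endpoint (30-day death, intervention, rebleeding, ICU
admission) computes per-stratum AUC with DeLong 95% CI, the Youden operating
point with exact binomial CIs, the accuracy band, and the unpaired DeLong
p-value for the between-stratum AUC difference.  One CSV per outcome under
results/.
"""

from pathlib import Path

from ugibrisk import patient_model, pipeline, synthetic_cohort
from ugibrisk.patient_model import OUTCOMES

ROOT = Path(__file__).resolve().parents[1]


def load_cohort():
    path = ROOT / "scratch" / "cohort.csv"
    if path.exists():
        rows, _ = patient_model.read_cohort(path)
        return rows
    return synthetic_cohort.generate(synthetic_cohort.default_config(seed=1))


def main() -> None:
    cohort = load_cohort()
    (ROOT / "results").mkdir(exist_ok=True)
    for outcome in OUTCOMES:
        table = pipeline.run_between_group(cohort, outcome)
        frame = pipeline.between_table_frame(table)
        out = ROOT / "results" / f"between_{outcome}.csv"
        frame.to_csv(out, index=False)
        print(f"\n== {outcome} ==")
        print(frame[["system", "elderly_auc", "younger_auc",
                     "elderly_band", "younger_band", "p_between"]]
              .to_string(index=False))
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
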