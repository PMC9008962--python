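#!/usr/bin/env python
"""Pairwise paired-DeLong comparison of the six systems within each stratum.

For each stratum and endpoint: per-system AUC plus the symmetric 6x6 matrix
of paired DeLong p-values over the 15 system pairs.  Writes
results/within_<stratum>_<outcome>_auc.csv and ..._p.csv.
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
    elderly, younger = patient_model.stratify(cohort)
    (ROOT / "results").mkdir(exist_ok=True)
    for name, part in (("elderly", elderly), ("younger", younger)):
        for outcome in OUTCOMES:
            table = pipeline.run_within_group(part, outcome)
            auc, pmat = pipeline.within_table_frames(table)
            auc.to_csv(ROOT / "results" / f"within_{name}_{outcome}_auc.csv",
                       index=False)
            pmat.round(4).to_csv(ROOT / "results" / f"within_{name}_{outcome}_p.csv")
        print(f"{name}: wrote AUC and pairwise-p tables for {len(OUTCOMES)} outcomes")
    print("example (elderly, 30-day death):")
    table = pipeline.run_within_group(elderly, "death_30d")
    auc, pmat = pipeline.within_table_frames(table)
    print(auc.to_string(index=False))
    print(pmat.round(3).to_string())


if __name__ == "__main__":
    main()
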