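"""End-to-end comparison pipeline.

Given a cohort (ingested or generated), score every admission with all six
systems and produce the two analysis shapes of the study design:

* between-group: per outcome and per system, AUC (95% CI), Youden
  sensitivity/specificity (95% CI) and accuracy band within each age stratum,
  plus the unpaired DeLong p-value for the elderly-vs-younger AUC difference
  (disjoint patients, covariance 0);
* within-group: per outcome, a symmetric 6 x 6 matrix of paired DeLong
  p-values over the 15 system pairs, computed from per-patient paired scores.

Every number in a table is reproducible by calling the roc_delong functions
directly on the scored cohort; the pipeline holds no private math.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .patient_model import CohortRow, OUTCOMES, Stratum, stratify
from .risk_scores import SCORERS, SYSTEM_ORDER, SYSTEMS
from .roc_delong import (
    AucResult,
    CutoffResult,
    accuracy_band,
    auc_empirical,
    compare_paired,
    compare_unpaired,
    orient,
    youden_cutoff,
)


def score_frame(cohort: Sequence[CohortRow]) -> pd.DataFrame:
    """One row per admission: six score totals, outcome labels, stratum."""
    data: dict[str, list] = {s: [] for s in SYSTEM_ORDER}
    for row in cohort:
        for s in SYSTEM_ORDER:
            data[s].append(SCORERS[s](row.record).total)
    frame = pd.DataFrame(data)
    for o in OUTCOMES:
        frame[o] = [getattr(r.outcomes, o) for r in cohort]
    frame["stratum"] = [r.stratum.value for r in cohort]
    return frame


def components_json(cohort: Sequence[CohortRow]) -> list[dict]:
    """Component-level breakdown of all six scores per admission."""
    out = []
    for row in cohort:
        entry = {"stratum": row.stratum.value}
        for s in SYSTEM_ORDER:
            res = SCORERS[s](row.record)
            entry[s] = {"total": res.total, "components": res.components}
        out.append(entry)
    return out


@dataclass
class SystemRow:
    """One system's between-group row: per-stratum AUC + cutoff + band."""

    system: str
    elderly_auc: AucResult | None
    younger_auc: AucResult | None
    elderly_cutoff: CutoffResult | None
    younger_cutoff: CutoffResult | None
    p_between: float | None
    flag: str | None = None

    @property
    def elderly_band(self) -> str | None:
        return accuracy_band(self.elderly_auc.auc) if self.elderly_auc else None

    @property
    def younger_band(self) -> str | None:
        return accuracy_band(self.younger_auc.auc) if self.younger_auc else None


@dataclass
class ComparisonTable:
    """Per-outcome result table; between-group rows or a pairwise p matrix."""

    outcome: str
    design: str  # "between" or "within"
    rows: list[SystemRow] = field(default_factory=list)
    auc: dict[str, AucResult] = field(default_factory=dict)
    pairwise_p: pd.DataFrame | None = None


def _stratum_scores(rows: Sequence[CohortRow], system: str) -> np.ndarray:
    scorer = SCORERS[system]
    return np.array([scorer(r.record).total for r in rows], dtype=float)


def _labels(rows: Sequence[CohortRow], outcome: str) -> np.ndarray:
    return np.array([getattr(r.outcomes, outcome) for r in rows], dtype=bool)


def run_between_group(cohort: Sequence[CohortRow], outcome: str) -> ComparisonTable:
    """Elderly-vs-younger comparison of all six systems for one outcome."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    elderly, younger = stratify(cohort)
    table = ComparisonTable(outcome=outcome, design="between")
    for system in SYSTEM_ORDER:
        direction = SYSTEMS[system].direction
        per_stratum: dict[str, tuple[AucResult, CutoffResult] | None] = {}
        flag = None
        for name, rows in (("elderly", elderly), ("younger", younger)):
            scores = _stratum_scores(rows, system)
            labels = _labels(rows, outcome)
            try:
                res = auc_empirical(orient(scores, direction), labels)
                cut = youden_cutoff(scores, labels, direction)
                per_stratum[name] = (res, cut)
            except ValueError as e:
                per_stratum[name] = None
                flag = f"{name}: {e}"
        e, y = per_stratum["elderly"], per_stratum["younger"]
        p = compare_unpaired(e[0], y[0]).p if (e and y) else None
        table.rows.append(
            SystemRow(
                system=system,
                elderly_auc=e[0] if e else None,
                younger_auc=y[0] if y else None,
                elderly_cutoff=e[1] if e else None,
                younger_cutoff=y[1] if y else None,
                p_between=p,
                flag=flag,
            )
        )
    return table


def run_within_group(
    rows: Sequence[CohortRow], outcome: str, holm: bool = False
) -> ComparisonTable:
    """Pairwise paired-DeLong comparison of the six systems in one stratum.

    ``holm=True`` applies Holm step-down correction across the 15 unique
    pairs; off by default (raw p-values, as such matrices are usually
    reported).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    labels = _labels(rows, outcome)
    oriented = {
        s: orient(_stratum_scores(rows, s), SYSTEMS[s].direction)
        for s in SYSTEM_ORDER
    }
    table = ComparisonTable(outcome=outcome, design="within")
    for s in SYSTEM_ORDER:
        table.auc[s] = auc_empirical(oriented[s], labels)
    p = pd.DataFrame(np.nan, index=list(SYSTEM_ORDER), columns=list(SYSTEM_ORDER))
    pairs = [
        (a, b)
        for i, a in enumerate(SYSTEM_ORDER)
        for b in SYSTEM_ORDER[i + 1:]
    ]
    raw = [compare_paired(oriented[a], oriented[b], labels).p for a, b in pairs]
    if holm:
        from statsmodels.stats.multitest import multipletests

        raw = list(multipletests(raw, method="holm")[1])
    for (a, b), pv in zip(pairs, raw):
        p.loc[a, b] = p.loc[b, a] = pv
    table.pairwise_p = p
    return table


def significance_band(p: float) -> str:
    """Render a p-value the way the comparison tables print it."""
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return f"{p:.3f}"


def _fmt_auc(res: AucResult | None) -> str:
    if res is None:
        return "NA"
    return f"{res.auc:.3f} ({res.ci95[0]:.3f}-{res.ci95[1]:.3f})"


def _fmt_pct(value: float, ci: tuple[float, float]) -> str:
    return f"{100 * value:.1f} ({100 * ci[0]:.1f}-{100 * ci[1]:.1f})"


def between_table_frame(table: ComparisonTable) -> pd.DataFrame:
    """Formatted between-group table: AUC (95%CI), sens/spec % (95%CI),
    accuracy bands and the unpaired p-value, elderly/younger per system."""
    recs = []
    for row in table.rows:
        rec = {"outcome": table.outcome, "system": row.system}
        for name, res, cut in (
            ("elderly", row.elderly_auc, row.elderly_cutoff),
            ("younger", row.younger_auc, row.younger_cutoff),
        ):
            rec[f"{name}_auc"] = _fmt_auc(res)
            rec[f"{name}_band"] = accuracy_band(res.auc) if res else "NA"
            if cut is not None:
                rec[f"{name}_cutoff"] = cut.threshold
                rec[f"{name}_sensitivity"] = _fmt_pct(cut.sensitivity, cut.sens_ci95)
                rec[f"{name}_specificity"] = _fmt_pct(cut.specificity, cut.spec_ci95)
            else:
                rec[f"{name}_cutoff"] = np.nan
                rec[f"{name}_sensitivity"] = rec[f"{name}_specificity"] = "NA"
        rec["p_between"] = significance_band(row.p_between) if row.p_between is not None else "NA"
        rec["p_between_raw"] = row.p_between
        rec["flag"] = row.flag
        recs.append(rec)
    return pd.DataFrame(recs)


def within_table_frames(table: ComparisonTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(AUC summary, raw pairwise p matrix) for a within-group table."""
    auc = pd.DataFrame(
        {
            "system": list(SYSTEM_ORDER),
            "auc": [table.auc[s].auc for s in SYSTEM_ORDER],
            "band": [accuracy_band(table.auc[s].auc) for s in SYSTEM_ORDER],
        }
    )
    return auc, table.pairwise_p.copy()


def plot_roc(cohort: Sequence[CohortRow], outcome: str, path) -> None:
    """Convenience overlay of the six systems' ROC curves for one outcome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .roc_delong import roc_curve

    labels = _labels(cohort, outcome)
    fig, ax = plt.subplots(figsize=(5, 5))
    for s in SYSTEM_ORDER:
        scores = _stratum_scores(cohort, s)
        curve = roc_curve(scores, labels, SYSTEMS[s].direction)
        order = np.argsort(1 - curve.specificity)
        ax.plot((1 - curve.specificity)[order], curve.sensitivity[order], label=s)
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(outcome)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
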