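"""Empirical ROC analysis with DeLong variance and AUC comparison tests.

The empirical AUC is the normalized Mann-Whitney statistic with the half-tie
kernel: psi(X, Y) = 1 if X > Y, 1/2 if X = Y, 0 if X < Y, averaged over all
(positive, negative) score pairs.  Its variance follows DeLong's structural
components

    V10(i) = mean_j psi(X_i, Y_j)      (one per positive)
    V01(j) = mean_i psi(X_i, Y_j)      (one per negative)
    Var(AUC) = S10/m + S01/n

with S10, S01 the sample variances of the components and m, n the class
sizes; the covariance between two scores evaluated on the SAME patients uses
the sample covariances of their components.  Two AUCs are compared by the
normal statistic z = (A_a - A_b)/sqrt(V_a + V_b - 2C); for disjoint cohorts
the covariance is zero.  Components are computed in O(N log N) via midranks.

Operating points: after orientation (scores negated for lower-is-worse
systems such as the T-score) a patient is test-positive when score >=
threshold.  The reported cutoff maximizes the Youden index J = sensitivity +
specificity - 1; sensitivity/specificity carry exact Clopper-Pearson 95%
binomial intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .risk_scores import HIGHER_IS_WORSE, LOWER_IS_WORSE

Z_95 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class RocCurve:
    """Ordered operating points for one score against one binary outcome.

    Thresholds are in oriented units (higher = higher risk) and run from
    -inf (everyone test-positive) to +inf (no one test-positive), so
    sensitivity is non-increasing along the curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point, threshold on the original score scale.

    Positivity is score >= threshold for higher-is-worse systems and
    score <= threshold for lower-is-worse systems.
    """

    threshold: float
    sensitivity: float
    specificity: float
    sens_ci95: tuple[float, float]
    spec_ci95: tuple[float, float]


@dataclass(frozen=True)
class AucComparison:
    auc_a: AucResult
    auc_b: AucResult
    covariance: float
    z: float
    p: float


def orient(scores, direction: str) -> np.ndarray:
    """Return scores with higher = higher risk (negates lower-is-worse)."""
    scores = np.asarray(scores, dtype=float)
    if direction == HIGHER_IS_WORSE:
        return scores
    if direction == LOWER_IS_WORSE:
        return -scores
    raise ValueError(f"unknown direction {direction!r}")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "AUC undefined: need at least one positive and one negative label"
        )
    return pos, neg


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """Midrank computation of AUC and the DeLong components V10, V01."""
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return auc, v10, v01


def auc_value(scores, labels) -> float:
    """Empirical AUC (half-tie Mann-Whitney kernel) without variance."""
    pos, neg = _split(scores, labels)
    auc, _, _ = _structural_components(pos, neg)
    return float(auc)


def delong_variance(scores, labels) -> float:
    """DeLong variance of the empirical AUC; needs >= 2 of each class."""
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("DeLong variance needs >= 2 positives and >= 2 negatives")
    _, v10, v01 = _structural_components(pos, neg)
    return float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))


def delong_covariance(scores_a, scores_b, labels) -> float:
    """DeLong covariance of two AUCs computed on the same patients."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    if len(pos_a) < 2 or len(neg_a) < 2:
        raise ValueError("DeLong covariance needs >= 2 positives and >= 2 negatives")
    _, v10_a, v01_a = _structural_components(pos_a, neg_a)
    _, v10_b, v01_b = _structural_components(pos_b, neg_b)
    s10 = np.cov(v10_a, v10_b, ddof=1)[0, 1]
    s01 = np.cov(v01_a, v01_b, ddof=1)[0, 1]
    return float(s10 / len(pos_a) + s01 / len(neg_a))


def auc_empirical(scores, labels) -> AucResult:
    """Empirical AUC with DeLong variance and normal-approximation 95% CI.

    The CI is auc +/- 1.96 * sqrt(variance), clamped to [0, 1].
    """
    pos, neg = _split(scores, labels)
    auc, v10, v01 = _structural_components(pos, neg)
    if len(pos) >= 2 and len(neg) >= 2:
        var = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
    else:
        var = float("nan")
    half = Z_95 * np.sqrt(var)
    lo = float(max(0.0, auc - half))
    hi = float(min(1.0, auc + half))
    return AucResult(auc=float(auc), variance=var, ci95=(lo, hi),
                     n_pos=len(pos), n_neg=len(neg))


def _normal_compare(auc_a: AucResult, auc_b: AucResult, cov: float) -> AucComparison:
    denom2 = auc_a.variance + auc_b.variance - 2.0 * cov
    diff = auc_a.auc - auc_b.auc
    if denom2 <= 0.0:
        if diff == 0.0:
            return AucComparison(auc_a, auc_b, cov, z=0.0, p=1.0)
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / float(np.sqrt(denom2))
    p = float(2.0 * norm.sf(abs(z)))
    return AucComparison(auc_a, auc_b, cov, z=float(z), p=p)


def compare_paired(scores_a, scores_b, labels) -> AucComparison:
    """DeLong test for two scores measured on the same patients."""
    ra = auc_empirical(scores_a, labels)
    rb = auc_empirical(scores_b, labels)
    cov = delong_covariance(scores_a, scores_b, labels)
    return _normal_compare(ra, rb, cov)


def compare_unpaired(result_a: AucResult, result_b: AucResult) -> AucComparison:
    """DeLong-variance normal test for AUCs from disjoint cohorts (cov = 0)."""
    return _normal_compare(result_a, result_b, 0.0)


def roc_curve(scores, labels, direction: str = HIGHER_IS_WORSE) -> RocCurve:
    """Empirical ROC over thresholds at every observed score value plus the
    degenerate -inf/+inf endpoints, in oriented units."""
    oriented = orient(scores, direction)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = _split(oriented, labels)
    thresholds = np.concatenate(
        [[-np.inf], np.unique(oriented), [np.inf]]
    )
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, direction=direction)


def youden_cutoff(scores, labels, direction: str = HIGHER_IS_WORSE) -> CutoffResult:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties broken toward higher sensitivity, then the lower (oriented)
    threshold.  The returned threshold is on the original score scale;
    confidence intervals are exact Clopper-Pearson.
    """
    oriented = orient(scores, direction)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = _split(oriented, labels)
    m, n = len(pos), len(neg)

    candidates = np.unique(oriented)
    if len(candidates) == 1:
        warnings.warn("degenerate ROC: all scores identical; returning the "
                      "all-positive endpoint", stacklevel=2)
        candidates = np.array([candidates[0]])

    best = None  # (J, sens, -threshold) lexicographic max
    for t in candidates:
        tp = int((pos >= t).sum())
        tn = int((neg < t).sum())
        sens = tp / m
        spec = tn / n
        key = (sens + spec - 1.0, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, tp, tn)
    _, t, tp, tn = best
    sens, spec = tp / m, tn / n
    sens_ci = proportion_confint(tp, m, alpha=0.05, method="beta")
    spec_ci = proportion_confint(tn, n, alpha=0.05, method="beta")
    threshold = float(-t) if direction == LOWER_IS_WORSE else float(t)
    return CutoffResult(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        sens_ci95=(float(sens_ci[0]), float(sens_ci[1])),
        spec_ci95=(float(spec_ci[0]), float(spec_ci[1])),
    )


def accuracy_band(auc: float) -> str:
    """Discrimination band: <=0.5 non-informative, (0.5,0.7] poor,
    (0.7,0.9] fair, >0.9 good."""
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"AUC out of range: {auc}")
    if auc <= 0.5:
        return "non-informative"
    if auc <= 0.7:
        return "poor"
    if auc <= 0.9:
        return "fair"
    return "good"
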