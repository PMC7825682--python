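"""ROC/AUC analysis, Youden cutoff selection, diagnostic-test metrics,
and the nonparametric rank tests used around them.

The ROC treats a higher score (neck circumference) as evidence for
the positive class (OSA). The AUC equals the probability that a
random positive outscores a random negative (ties count one half),
which is the Mann–Whitney U statistic normalized by n_pos * n_neg.
Confidence intervals use the Hanley–McNeil standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "CutoffMetrics",
    "RankTestResult",
    "roc_auc",
    "auc_confidence_interval",
    "likelihood_ratios",
    "cutoff_metrics_table",
    "youden_optimal_cutoff",
    "youden_from_rates",
    "spearman_rho",
    "mann_whitney_u",
]


@dataclass(frozen=True)
class RocResult:
    """ROC curve points, AUC, and its normal-approximation CI."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int
    level: float


@dataclass(frozen=True)
class CutoffMetrics:
    """Diagnostic metrics of the test ``score > cutoff``."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float


@dataclass(frozen=True)
class RankTestResult:
    """Statistic (U or rho), two-sided p-value, group sizes."""

    statistic: float
    p_value: float
    n: tuple[int, ...]


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    return pos, neg


def auc_confidence_interval(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley–McNeil normal-quantile interval for the AUC, clipped to [0, 1].

    For a degenerate AUC of exactly 0 or 1 the standard error is 0 and
    the interval collapses to a point.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(auc - z * se, 0.0), min(auc + z * se, 1.0))


def roc_auc(scores, labels, level: float = 0.95) -> RocResult:
    """ROC curve and trapezoidal AUC with higher score as positive.

    The curve has one point per distinct score used as threshold
    (test-positive iff score > threshold); tied scores contribute
    diagonal segments, so the trapezoidal area equals the tie-corrected
    Mann–Whitney probability U / (n_pos * n_neg).
    """
    pos, neg = _split(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float((pos > t).mean()))
        fpr.append(float((neg > t).mean()))
    tpr.append(1.0)
    fpr.append(1.0)
    auc = float(np.trapezoid(tpr, fpr))
    lo, hi = auc_confidence_interval(auc, len(pos), len(neg), level)
    return RocResult(
        fpr=tuple(fpr),
        tpr=tuple(tpr),
        thresholds=tuple(float(t) for t in thresholds),
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        n_positive=len(pos),
        n_negative=len(neg),
        level=level,
    )


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """(LR+, LR-) from sensitivity and specificity.

    LR+ = sens / (1 - spec) (infinite at specificity 1);
    LR- = (1 - sens) / spec (infinite at specificity 0).
    """
    lr_pos = sensitivity / (1.0 - specificity) if specificity < 1.0 else math.inf
    lr_neg = (1.0 - sensitivity) / specificity if specificity > 0.0 else math.inf
    return lr_pos, lr_neg


def cutoff_metrics_table(
    scores, labels, cutoffs: Sequence[float]
) -> list[CutoffMetrics]:
    """Sensitivity/specificity/PPV/NPV/LR+/LR- at each cutoff.

    Test-positive iff score > cutoff. Sensitivity is non-increasing and
    specificity non-decreasing in the cutoff by construction.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoff list must not be empty")
    pos, neg = _split(scores, labels)
    out = []
    for c in cutoffs:
        tp = int((pos > c).sum())
        fn = len(pos) - tp
        fp = int((neg > c).sum())
        tn = len(neg) - fp
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        lr_pos, lr_neg = likelihood_ratios(sens, spec)
        out.append(
            CutoffMetrics(
                cutoff=float(c),
                sensitivity=sens,
                specificity=spec,
                ppv=tp / (tp + fp) if (tp + fp) else float("nan"),
                npv=tn / (tn + fn) if (tn + fn) else float("nan"),
                lr_pos=lr_pos,
                lr_neg=lr_neg,
            )
        )
    return out


def youden_from_rates(
    cutoffs: Sequence[float],
    sensitivities: Sequence[float],
    specificities: Sequence[float],
) -> float:
    """Cutoff maximizing Youden's J = sens + spec - 1 over given rows.

    Ties break toward the smaller cutoff.
    """
    if not (len(cutoffs) == len(sensitivities) == len(specificities) > 0):
        raise ValueError("need equal-length, non-empty rate vectors")
    best_c, best_j = None, -math.inf
    for c, sn, sp in sorted(zip(cutoffs, sensitivities, specificities)):
        j = sn + sp - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def youden_optimal_cutoff(
    scores, labels, candidate_cutoffs: Optional[Sequence[float]] = None
) -> float:
    """Youden-optimal cutoff over the candidates.

    Default candidates are the integer values spanning the observed
    score range, mirroring whole-centimetre NC cutoffs.
    """
    s = np.asarray(scores, dtype=float)
    if candidate_cutoffs is None:
        candidate_cutoffs = np.arange(math.floor(s.min()), math.ceil(s.max()) + 1.0)
    table = cutoff_metrics_table(scores, labels, list(candidate_cutoffs))
    return youden_from_rates(
        [m.cutoff for m in table],
        [m.sensitivity for m in table],
        [m.specificity for m in table],
    )


def spearman_rho(x, y) -> RankTestResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t approximation. Raises on constant
    input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return RankTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), n=(len(x),)
    )


def mann_whitney_u(x, y) -> RankTestResult:
    """Mann–Whitney U for group *x* versus *y* (U counts pairs where x
    exceeds y, ties half) with a continuity-corrected normal p-value.

    U / (n1 * n2) equals the ROC AUC of the pooled scores with *x* as
    the positive class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
    )
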