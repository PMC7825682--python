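"""Community-level CPAP response: transition tables, response classes,
parameter representation, and NC-threshold evaluation.

A community's *AHI improvement* is the percentage of its severe
(pre-treatment) patients who end in the norm or mild class after one
CPAP night. Communities at or above a threshold improvement (default
85%) form the *best* response class; the rest form the *good* class.
A neck-circumference cutoff is then judged as a classifier of the two
response classes: predicted good iff NC <= cutoff, predicted best iff
NC > cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import ClassProfile, PatientRecord, Severity, classify_ahi_severity

__all__ = [
    "severity_transition_table",
    "ahi_improvement",
    "improvements_by_community",
    "label_response_classes",
    "ResponseClassLabeling",
    "parameter_community_map",
    "ContingencyMetrics",
    "NcThresholdEvaluation",
    "contingency_from_counts",
    "evaluate_nc_threshold",
]

logger = logging.getLogger(__name__)

_SEVERITY_NAMES = [s.name for s in Severity]


def _with_after(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    recs = list(records)
    kept = [r for r in recs if r.ahi_after is not None]
    dropped = len(recs) - len(kept)
    if dropped:
        logger.warning("excluded %d record(s) without post-treatment AHI", dropped)
    return kept


def severity_transition_table(
    records: Iterable[PatientRecord], partition: Mapping[str, int]
) -> pd.DataFrame:
    """Per-community severity-class fractions before and after CPAP.

    Returns a DataFrame indexed by community id with a (phase, class)
    column MultiIndex; each four-class block sums to 1 per community.
    Records lacking a post-treatment AHI are excluded (logged).
    """
    rows = []
    for r in _with_after(records):
        rows.append(
            {
                "community": partition[r.id],
                "before": classify_ahi_severity(r.ahi_before).name,
                "after": classify_ahi_severity(r.ahi_after).name,
            }
        )
    df = pd.DataFrame(rows)
    out = {}
    for phase in ("before", "after"):
        frac = (
            df.groupby("community")[phase]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=_SEVERITY_NAMES, fill_value=0.0)
        )
        for cls in _SEVERITY_NAMES:
            out[(phase, cls)] = frac[cls]
    table = pd.DataFrame(out)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["phase", "class"])
    return table.sort_index()


def ahi_improvement(
    records: Iterable[PatientRecord],
    community_ids: Optional[set] = None,
    partition: Optional[Mapping[str, int]] = None,
    mode: str = "reclassified",
) -> float:
    """AHI improvement (percent) for a set of patients.

    ``reclassified`` (default): among patients severe before CPAP, the
    percentage whose post-treatment class is norm or mild.
    ``sev_reduction``: relative drop in the severe head count,
    100 * (n_sev_before - n_sev_after) / n_sev_before.

    When *community_ids* and *partition* are given, only members of
    those communities count. Raises ``ValueError`` when no patient is
    severe before treatment.
    """
    if mode not in ("reclassified", "sev_reduction"):
        raise ValueError(f"unknown improvement mode {mode!r}")
    recs = _with_after(records)
    if community_ids is not None:
        if partition is None:
            raise ValueError("community_ids requires a partition")
        recs = [r for r in recs if partition[r.id] in community_ids]
    sev_before = [r for r in recs if classify_ahi_severity(r.ahi_before) == Severity.sev]
    if not sev_before:
        raise ValueError("AHI improvement undefined: no patient severe before CPAP")
    if mode == "reclassified":
        improved = sum(
            classify_ahi_severity(r.ahi_after) <= Severity.mild for r in sev_before
        )
        return 100.0 * improved / len(sev_before)
    sev_after = sum(
        classify_ahi_severity(r.ahi_after) == Severity.sev for r in recs
    )
    return 100.0 * (len(sev_before) - sev_after) / len(sev_before)


def improvements_by_community(
    records: Iterable[PatientRecord],
    partition: Mapping[str, int],
    mode: str = "reclassified",
) -> dict:
    """AHI improvement per community id."""
    recs = list(records)
    return {
        c: ahi_improvement(recs, community_ids={c}, partition=partition, mode=mode)
        for c in sorted(set(partition.values()))
    }


@dataclass(frozen=True)
class ResponseClassLabeling:
    """best/good label and improvement percentage per community."""

    labels: dict  # community id -> "best" | "good"
    improvement: dict  # community id -> percent
    best_threshold: float

    def communities(self, label: str) -> set:
        return {c for c, l in self.labels.items() if l == label}


def label_response_classes(
    improvements: Mapping, best_threshold: float = 85.0
) -> ResponseClassLabeling:
    """Label communities *best* (improvement >= threshold) or *good*."""
    if not improvements:
        raise ValueError("need at least one community")
    labels = {
        c: ("best" if imp >= best_threshold else "good")
        for c, imp in improvements.items()
    }
    return ResponseClassLabeling(
        labels=labels, improvement=dict(improvements), best_threshold=best_threshold
    )


_BOOL_SLOTS = ("hbp", "obese", "thick_neck", "sleepiness")


def parameter_community_map(
    profiles: Mapping[str, ClassProfile],
    partition: Mapping[str, int],
    representative_threshold: float = 0.70,
) -> pd.DataFrame:
    """Majority class and prevalence of each parameter per community.

    A class is *representative* when its prevalence reaches the
    threshold (>=); otherwise the cell is marked "-". Boolean slots
    report "1"/"0" for class direction, gender reports "M"/"F", the
    age group its index.
    """
    rows = []
    for c in sorted(set(partition.values())):
        members = [profiles[pid] for pid, cc in partition.items() if cc == c]
        n = len(members)
        for slot in ("gender",) + _BOOL_SLOTS + ("age_group",):
            if slot == "gender":
                values = [p.gender_class for p in members]
            elif slot == "age_group":
                values = [p.age_group for p in members]
            else:
                values = [int(getattr(p, slot)) for p in members]
            counts = pd.Series(values).value_counts()
            majority = counts.index[0]
            prevalence = counts.iloc[0] / n
            rows.append(
                {
                    "community": c,
                    "parameter": slot,
                    "majority_class": str(majority),
                    "prevalence": prevalence,
                    "representative": prevalence >= representative_threshold,
                    "display": (
                        str(majority)
                        if prevalence >= representative_threshold
                        else "-"
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyMetrics:
    """2x2 classification outcome with its derived rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")


@dataclass(frozen=True)
class NcThresholdEvaluation:
    """Evaluation of one NC cutoff against the response-class labeling.

    ``pred_good_counts``/``pred_best_counts`` hold per-community head
    counts in the two predicted groups; ``good``/``best`` are the
    contingency metrics with the respective class as positive. The two
    orientations describe complementary classifiers on one table, so
    good.tpr == best.tnr and vice versa.
    """

    cutoff: float
    pred_good_counts: dict
    pred_best_counts: dict
    good: ContingencyMetrics
    best: ContingencyMetrics


def contingency_from_counts(
    pred_good_counts: Mapping,
    pred_best_counts: Mapping,
    good_communities: set,
    cutoff: float = float("nan"),
) -> NcThresholdEvaluation:
    """Build the cutoff evaluation from per-community head counts.

    *pred_good_counts* are patients with NC <= cutoff per community,
    *pred_best_counts* those with NC > cutoff; *good_communities* is
    the set of community ids labeled good.
    """
    communities = set(pred_good_counts) | set(pred_best_counts)
    gp = sum(pred_good_counts.get(c, 0) for c in communities if c in good_communities)
    gn = sum(pred_best_counts.get(c, 0) for c in communities if c in good_communities)
    bp = sum(pred_good_counts.get(c, 0) for c in communities if c not in good_communities)
    bn = sum(pred_best_counts.get(c, 0) for c in communities if c not in good_communities)
    # good orientation: positive = member of a good community, predicted
    # positive = NC <= cutoff
    good = ContingencyMetrics(tp=gp, fn=gn, fp=bp, tn=bn)
    best = ContingencyMetrics(tp=bn, fn=bp, fp=gn, tn=gp)
    return NcThresholdEvaluation(
        cutoff=cutoff,
        pred_good_counts={c: int(pred_good_counts.get(c, 0)) for c in sorted(communities)},
        pred_best_counts={c: int(pred_best_counts.get(c, 0)) for c in sorted(communities)},
        good=good,
        best=best,
    )


def evaluate_nc_threshold(
    records: Iterable[PatientRecord],
    labeling: ResponseClassLabeling,
    partition: Mapping[str, int],
    cutoff: float,
) -> NcThresholdEvaluation:
    """Judge an NC cutoff as a classifier of the two response classes.

    Patients with NC <= cutoff are predicted *good*, the rest *best*;
    the truth is community membership per *labeling*.
    """
    pred_good: dict = {}
    pred_best: dict = {}
    for r in records:
        c = partition[r.id]
        if c not in labeling.labels:
            raise ValueError(f"community {c} of patient {r.id} is not labeled")
        bucket = pred_good if r.neck_circumference <= cutoff else pred_best
        bucket[c] = bucket.get(c, 0) + 1
    return contingency_from_counts(
        pred_good, pred_best, labeling.communities("good"), cutoff=cutoff
    )
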